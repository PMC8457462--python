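"""Alignment handling, substitution models, and the pruning likelihood
checked against exhaustive enumeration over internal states."""

import itertools
import math

import numpy as np
import pytest

from carabclock.prior_clock import ClockModel, branch_rate_vector
from carabclock.seqlike import (
    Alignment,
    AlignmentError,
    PartitionBlock,
    PartitionScheme,
    SubstitutionModel,
    compress_patterns,
    discrete_gamma_rates,
    partition_sites,
    pruning_loglik,
    read_alignment,
)
from carabclock.synthetic_data import simulate_alignment, simulate_yule_tree
from carabclock.timetree import parse_newick


# ----------------------------------------------------------------------
# exhaustive likelihood oracle (independent of the pruning implementation)


def brute_force_loglik(alignment, tree, clock, model):
    """Sum over all internal-state assignments, averaged over gamma categories."""
    rates = branch_rate_vector(tree, clock)
    cat_rates = model.category_rates()
    nodes = tree.nodes()
    internals = [n for n in nodes if not n.is_tip]
    tips = {n.name: n for n in nodes if n.is_tip}
    pi = model.pi
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for site in range(alignment.length):
        site_lik = 0.0
        for cat_rate in cat_rates:
            pmats = {
                n.index: model.transition_matrix(
                    (n.parent.age - n.age) * rates[n.index] * cat_rate
                )
                for n in nodes
                if n.parent is not None
            }
            lik = 0.0
            for assignment in itertools.product(range(4), repeat=len(internals)):
                states = {n.index: s for n, s in zip(internals, assignment)}
                for taxon, seq in zip(alignment.taxa, alignment.sequences):
                    states[tips[taxon].index] = code[seq[site]]
                term = pi[states[tree.root.index]]
                for n in nodes:
                    if n.parent is not None:
                        term *= pmats[n.index][states[n.parent.index], states[n.index]]
                lik += term
            site_lik += lik / len(cat_rates)
        total += math.log(site_lik)
    return total


def random_instance(rng, max_taxa=4, max_sites=6):
    n = int(rng.integers(2, max_taxa + 1))
    tree = simulate_yule_tree(n, 1.0, rng)
    which = rng.integers(3)
    if which == 0:
        model = SubstitutionModel("JC69")
    elif which == 1:
        model = SubstitutionModel(
            "HKY", base_freqs=(0.3, 0.2, 0.15, 0.35), kappa=float(rng.uniform(0.5, 8))
        )
    else:
        model = SubstitutionModel(
            "HKY",
            base_freqs=(0.3, 0.2, 0.15, 0.35),
            kappa=float(rng.uniform(0.5, 8)),
            gamma_shape=float(rng.uniform(0.2, 2.0)),
        )
    clock = ClockModel("strict", mean_rate=float(rng.uniform(0.05, 0.5)))
    n_sites = int(rng.integers(1, max_sites + 1))
    aln = simulate_alignment(tree, clock, model, n_sites, rng)
    return aln, tree, clock, model


class TestPruning:
    def test_two_taxon_worked_value(self):
        tree = parse_newick("(A:1.0,B:1.0);")
        aln = Alignment(["A", "B"], ["A", "A"])
        ll = pruning_loglik(
            aln, tree, ClockModel("strict", mean_rate=0.1), models=SubstitutionModel("JC69")
        )
        # 1/4 * sum_r P_rA(0.1)^2 with P_AA = 1/4 + 3/4 exp(-0.4/3)
        assert ll == pytest.approx(-1.5793, abs=5e-4)

    def test_identical_sequences_zero_distance(self):
        tree = parse_newick("(A:1.0,B:1.0);")
        aln = Alignment(["A", "B"], ["G", "G"])
        ll = pruning_loglik(
            aln, tree, ClockModel("strict", mean_rate=1e-12),
            models=SubstitutionModel("JC69"),
        )
        assert ll == pytest.approx(math.log(0.25), abs=1e-6)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            aln, tree, clock, model = random_instance(rng)
            fast = pruning_loglik(aln, tree, clock, models=model)
            slow = brute_force_loglik(aln, tree, clock, model)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_rate_time_rescaling_invariance(self, rng):
        """Scaling ages by c and the rate by 1/c leaves the likelihood fixed."""
        tree = simulate_yule_tree(8, 1.0, rng)
        model = SubstitutionModel("HKY", kappa=3.0, gamma_shape=0.5)
        clock = ClockModel("strict", mean_rate=0.2)
        aln = simulate_alignment(tree, clock, model, 200, rng)
        base = pruning_loglik(aln, tree, clock, models=model)
        for c in (0.1, 3.7, 25.0):
            scaled = tree.copy()
            for node in scaled.postorder():
                node.age *= c
            clock_c = ClockModel("strict", mean_rate=0.2 / c)
            assert pruning_loglik(aln, scaled, clock_c, models=model) == pytest.approx(
                base, abs=1e-9
            )

    def test_gamma_single_category_matches_homogeneous(self, rng):
        tree = simulate_yule_tree(5, 1.0, rng)
        clock = ClockModel("strict", mean_rate=0.1)
        plain = SubstitutionModel("HKY", kappa=2.5)
        aln = simulate_alignment(tree, clock, plain, 100, rng)
        one_cat = SubstitutionModel("HKY", kappa=2.5, gamma_shape=0.7, n_categories=1)
        huge_alpha = SubstitutionModel("HKY", kappa=2.5, gamma_shape=1e8)
        base = pruning_loglik(aln, tree, clock, models=plain)
        assert pruning_loglik(aln, tree, clock, models=one_cat) == pytest.approx(base, abs=1e-9)
        assert pruning_loglik(aln, tree, clock, models=huge_alpha) == pytest.approx(base, abs=1e-5)

    def test_all_missing_column_contributes_nothing(self, rng):
        tree = simulate_yule_tree(4, 1.0, rng)
        clock = ClockModel("strict", mean_rate=0.1)
        model = SubstitutionModel("HKY", kappa=2.0, gamma_shape=0.5)
        aln = simulate_alignment(tree, clock, model, 50, rng)
        padded = Alignment(aln.taxa, [s + "N-?" for s in aln.sequences])
        assert pruning_loglik(padded, tree, clock, models=model) == pytest.approx(
            pruning_loglik(aln, tree, clock, models=model), abs=1e-9
        )

    def test_taxa_mismatch_raises(self, rng):
        tree = simulate_yule_tree(4, 1.0, rng)
        aln = Alignment(["x1", "x2"], ["AC", "AG"])
        with pytest.raises(AlignmentError, match="differ"):
            pruning_loglik(aln, tree, ClockModel("strict", mean_rate=0.1))


class TestTransitionMatrices:
    def test_jc_identity_at_zero(self):
        p = SubstitutionModel("JC69").transition_matrix(0.0)
        assert np.allclose(p, np.eye(4), atol=1e-12)

    def test_hky_kappa_one_uniform_equals_jc(self):
        jc = SubstitutionModel("JC69")
        hky = SubstitutionModel("HKY", kappa=1.0)
        for d in (0.01, 0.5, 2.0):
            assert np.allclose(hky.transition_matrix(d), jc.transition_matrix(d), atol=1e-12)

    def test_rows_sum_to_one_and_stationarity(self):
        for model in (
            SubstitutionModel("K80", kappa=4.0),
            SubstitutionModel("HKY", base_freqs=(0.4, 0.1, 0.2, 0.3), kappa=3.0),
            SubstitutionModel("GTR", base_freqs=(0.4, 0.1, 0.2, 0.3),
                              exchangeabilities=(1, 3, 0.5, 0.8, 4, 1)),
        ):
            for d in (0.0, 0.2, 1.0):
                p = model.transition_matrix(d)
                assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
            far = model.transition_matrix(1e3)
            assert np.allclose(far, np.tile(model.pi, (4, 1)), atol=1e-6)

    def test_rate_matrix_normalized(self):
        for model in (SubstitutionModel("JC69"), SubstitutionModel("GTR")):
            q = model.rate_matrix()
            assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
            assert -np.dot(model.pi, np.diag(q)) == pytest.approx(1.0)

    def test_batch_matches_scalar(self):
        model = SubstitutionModel("HKY", base_freqs=(0.3, 0.2, 0.15, 0.35), kappa=5.0)
        ds = np.array([0.0, 0.03, 0.7, 4.0])
        batch = model.transition_matrices(ds)
        for i, d in enumerate(ds):
            assert np.allclose(batch[i], model.transition_matrix(float(d)), atol=1e-12)

    def test_discrete_gamma_rates_mean_one(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(alpha, 4)
            assert rates.mean() == pytest.approx(1.0)
            assert np.all(np.diff(rates) > 0)


class TestPartitions:
    @pytest.mark.parametrize(
        "frame,expected_p3",
        [(1, [3, 6, 9]), (2, [1, 4, 7]), (3, [2, 5, 8])],
    )
    def test_2p_codon_split(self, frame, expected_p3):
        aln = Alignment(["a", "b"], ["ACGTACGTA", "ACGTACGTA"])
        scheme = PartitionScheme(
            (PartitionBlock("g", 1, 9, scheme="2P", frame=frame),)
        )
        parts = partition_sites(aln, scheme)
        # 1-based positions back from 0-based indices
        assert sorted(parts["g/p3"] + 1) == expected_p3
        assert sorted(np.concatenate([parts["g/p12"], parts["g/p3"]]) + 1) == list(range(1, 10))

    def test_np_block_single_list(self):
        aln = Alignment(["a", "b"], ["ACGTA", "ACGTA"])
        parts = partition_sites(aln, PartitionScheme.single(5))
        assert list(parts["all"]) == [0, 1, 2, 3, 4]

    def test_gaps_and_overlaps_rejected(self):
        aln = Alignment(["a", "b"], ["ACGTA", "ACGTA"])
        with pytest.raises(AlignmentError, match="gap"):
            partition_sites(aln, PartitionScheme((PartitionBlock("g", 1, 3),)))
        with pytest.raises(AlignmentError, match="overlap"):
            PartitionScheme(
                (PartitionBlock("g", 1, 3), PartitionBlock("h", 3, 5))
            )


class TestCompression:
    def test_identical_columns_single_pattern(self):
        aln = Alignment(["a", "b"], ["AAAA", "CCCC"])
        patterns, counts = compress_patterns(aln)
        assert patterns.shape[1] == 1
        assert counts.tolist() == [4.0]

    def test_distinct_columns_unit_multiplicities(self):
        aln = Alignment(["a", "b"], ["ACGT", "ACGA"])
        patterns, counts = compress_patterns(aln)
        assert patterns.shape[1] == 4
        assert counts.tolist() == [1.0] * 4

    def test_counts_sum_to_sites(self, rng):
        tree = simulate_yule_tree(6, 1.0, rng)
        aln = simulate_alignment(
            tree, ClockModel("strict", mean_rate=0.1), SubstitutionModel("JC69"), 321, rng
        )
        _, counts = compress_patterns(aln)
        assert counts.sum() == 321


class TestAlignmentIO:
    def test_fasta_round_trip(self, tmp_path):
        aln = Alignment(["s1", "s2", "s3"], ["ACGT", "ACGA", "AC-T"])
        path = tmp_path / "x.fasta"
        aln.write_fasta(str(path))
        again = read_alignment(str(path))
        assert again.taxa == aln.taxa
        assert again.sequences == aln.sequences

    def test_nexus_interleaved_equals_sequential(self, tmp_path):
        seqs = {"tax1": "ACGTACGT", "tax2": "ACGAACGA", "tax3": "TCGTACGA"}
        seq_block = "\n".join(f"{t} {s}" for t, s in seqs.items())
        inter_block = "\n".join(
            [f"{t} {s[:4]}" for t, s in seqs.items()]
            + [f"{t} {s[4:]}" for t, s in seqs.items()]
        )
        header = "#NEXUS\nbegin data;\ndimensions ntax=3 nchar=8;\n"
        seq_path = tmp_path / "seq.nex"
        seq_path.write_text(
            header + "format datatype=dna;\nmatrix\n" + seq_block + "\n;\nend;\n"
        )
        int_path = tmp_path / "int.nex"
        int_path.write_text(
            header
            + "format datatype=dna interleave=yes;\nmatrix\n"
            + inter_block
            + "\n;\nend;\n"
        )
        a = read_alignment(str(seq_path))
        b = read_alignment(str(int_path))
        assert a.taxa == b.taxa and a.sequences == b.sequences

    def test_ragged_input_names_offender(self):
        with pytest.raises(AlignmentError, match="bad_tax"):
            Alignment(["ok", "bad_tax"], ["ACGT", "ACG"])

    def test_illegal_symbols_rejected(self):
        with pytest.raises(AlignmentError, match="illegal"):
            Alignment(["a"], ["ACGX"])
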