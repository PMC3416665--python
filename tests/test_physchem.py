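"""Physico-chemical indices: Henderson–Hasselbalch charge model, bisection
pI, GRAVY, aromaticity, aliphatic and instability indices, pI histograms."""
import numpy as np
import pytest

from protniche import physchem as pc
from protniche.io_core import ValidationError
from protniche.physchem import (DEFAULT_PKA, DIPEPTIDE_INSTABILITY,
                                KYTE_DOOLITTLE, aliphatic_index, aromaticity,
                                bin_pi_distribution, gravy,
                                group_mean_sd_distribution, instability_index,
                                isoelectric_point, net_charge_at_pH)
from protniche.residues import RESIDUES
from protniche.synthetic_data import simulate_proteome


def random_peptides(seed, n, lo=20, hi=80):
    rng = np.random.default_rng(seed)
    res = np.array(list(RESIDUES))
    return ["".join(rng.choice(res, size=int(rng.integers(lo, hi))))
            for _ in range(n)]


def charge_oracle(sequence, pH, pka=DEFAULT_PKA):
    """Vectorised, independent evaluation of the charge formula."""
    pos = [(1, pka.nterm)] + [(sequence.count(a), pka.side[a]) for a in "HKR"]
    neg = [(1, pka.cterm)] + [(sequence.count(a), pka.side[a]) for a in "DECY"]
    total = sum(n / (1 + 10 ** (pH - k)) for n, k in pos)
    total -= sum(n / (1 + 10 ** (k - pH)) for n, k in neg)
    return total


class TestNetCharge:
    def test_group_at_its_pKa_contributes_half(self):
        # Lys side chains at pH == their pKa are exactly half-protonated:
        # the poly-K vs poly-G difference is n * 0.5.
        pH = DEFAULT_PKA.side["K"]
        diff = net_charge_at_pH("KKKKK", pH) - net_charge_at_pH("GGGGG", pH)
        assert diff == pytest.approx(5 * 0.5)

    def test_low_pH_limit_counts_positive_groups(self):
        # at pH 0, N-terminus + Lys are fully protonated (2 positive groups)
        assert net_charge_at_pH("GGKGG", 0.0) == pytest.approx(2.0, abs=1e-3)

    def test_hand_evaluation_of_formula(self):
        got = net_charge_at_pH("GGDGG", 7.0)
        assert got == pytest.approx(charge_oracle("GGDGG", 7.0), abs=1e-12)

    def test_unknown_residues_are_non_ionizable(self):
        assert net_charge_at_pH("GXG", 7.0) == net_charge_at_pH("GGG", 7.0)


class TestIsoelectricPoint:
    def test_charge_at_root_is_tiny(self):
        for seq in random_peptides(1, 100):
            pi = isoelectric_point(seq)
            assert abs(net_charge_at_pH(seq, pi)) <= 1e-3

    def test_acidic_sequence_below_basic_sequence(self):
        assert isoelectric_point("D" * 20) < isoelectric_point("K" * 20)

    def test_grid_search_oracle_agreement(self):
        """Bisection matches an independent 10^6-point grid minimiser of the
        |charge| curve to 2 decimals."""
        grid = np.linspace(0.0, 14.0, 1_000_001)
        for seq in ["GGKGG"] + random_peptides(2, 19):
            # vectorised oracle over the grid
            pos = [(1, DEFAULT_PKA.nterm)] + [
                (seq.count(a), DEFAULT_PKA.side[a]) for a in "HKR"]
            neg = [(1, DEFAULT_PKA.cterm)] + [
                (seq.count(a), DEFAULT_PKA.side[a]) for a in "DECY"]
            charges = sum(n / (1 + 10 ** (grid - k)) for n, k in pos)
            charges -= sum(n / (1 + 10 ** (k - grid)) for n, k in neg)
            oracle = grid[np.argmin(np.abs(charges))]
            assert isoelectric_point(seq) == pytest.approx(oracle, abs=0.005)

    def test_monotone_under_charged_appends(self):
        for seq in random_peptides(3, 100, lo=10, hi=40):
            base = isoelectric_point(seq)
            assert isoelectric_point(seq + "D") <= base + 1e-6
            assert isoelectric_point(seq + "K") >= base - 1e-6


class TestScalarIndices:
    def test_gravy_homopolymer_reads_scale(self):
        assert gravy("I" * 30) == pytest.approx(KYTE_DOOLITTLE["I"])

    def test_gravy_order_invariant(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert gravy(seq) == pytest.approx(gravy(seq[::-1]))

    def test_gravy_is_linear_in_composition(self):
        mix = "I" * 10 + "D" * 10
        assert gravy(mix) == pytest.approx(
            0.5 * (KYTE_DOOLITTLE["I"] + KYTE_DOOLITTLE["D"]))

    def test_gravy_all_ambiguous_is_error(self):
        with pytest.raises(ValidationError):
            gravy("XXXX")

    def test_aromaticity_extremes_and_tally(self, rng):
        assert aromaticity("FWYFWY") == 1.0
        assert aromaticity("A" * 10) == 0.0
        seq = "".join(rng.choice(list(RESIDUES), size=200))
        expected = sum(seq.count(a) for a in "FYW") / len(seq)
        assert aromaticity(seq) == pytest.approx(expected)

    def test_aliphatic_index_coefficients(self):
        assert aliphatic_index("A" * 25) == pytest.approx(100.0)
        assert aliphatic_index("G" * 25) == pytest.approx(0.0)
        assert aliphatic_index("L" * 25) == pytest.approx(390.0)

    def test_instability_single_dipeptide(self):
        w = DIPEPTIDE_INSTABILITY["W"]["W"]
        assert instability_index("WW") == pytest.approx(5 * w)

    def test_instability_homopolymer_closed_form(self):
        # Ala-Ala has weight 1, so a poly-Ala L-mer scores 10*(L-1)/L
        assert DIPEPTIDE_INSTABILITY["A"]["A"] == 1.0
        L = 37
        assert instability_index("A" * L) == pytest.approx(10 * (L - 1) / L)

    def test_instability_matches_loop_oracle(self, rng):
        seq = "".join(rng.choice(list(RESIDUES), size=30))
        total = 0.0
        for i in range(len(seq) - 1):
            total += DIPEPTIDE_INSTABILITY[seq[i]][seq[i + 1]]
        assert instability_index(seq) == pytest.approx(10 * total / len(seq))

    def test_instability_needs_two_residues(self):
        with pytest.raises(ValidationError):
            instability_index("A")


class TestPIDistribution:
    def test_point_mass_lands_in_half_open_bin(self):
        d = bin_pi_distribution([5.2] * 10)
        i = d.bin_edges.index(5.0)
        assert d.percentages[i] == pytest.approx(100.0)

    def test_two_values_split_evenly(self):
        d = bin_pi_distribution([4.0, 10.0])
        by_bin = dict(zip(d.bin_edges, d.percentages))
        assert by_bin[4.0] == pytest.approx(50.0)
        assert by_bin[10.0] == pytest.approx(50.0)

    def test_mixture_histogram_matches_independent_tally(self, rng):
        values = np.concatenate([rng.normal(5.2, 0.4, 500),
                                 rng.normal(9.5, 0.5, 500)])
        d = bin_pi_distribution(values)
        clamped = np.clip(values, 2.0, 14.0 - 1e-9)
        counts, _ = np.histogram(clamped, bins=np.array(d.bin_edges))
        assert np.allclose(d.percentages, counts / 10.0, atol=1e-9)
        assert sum(d.percentages) == pytest.approx(100.0, abs=1e-6)

    def test_out_of_range_values_clamp_into_end_bins(self):
        d = bin_pi_distribution([0.5, 13.99])
        assert d.percentages[0] == pytest.approx(50.0)
        assert d.percentages[-1] == pytest.approx(50.0)


class TestGroupDistribution:
    def test_identical_distributions_have_zero_sd(self):
        d = bin_pi_distribution([5.0, 9.0, 9.2], organism_id="a")
        g = group_mean_sd_distribution([d, d, d], label="g")
        assert all(s == 0.0 for s in g.sd_percentages)
        assert np.allclose(g.mean_percentages, d.percentages)

    def test_two_distributions_mean_is_midpoint(self):
        d1 = bin_pi_distribution([4.0], organism_id="a")
        d2 = bin_pi_distribution([10.0], organism_id="b")
        g = group_mean_sd_distribution([d1, d2])
        mid = 0.5 * (np.array(d1.percentages) + np.array(d2.percentages))
        assert np.allclose(g.mean_percentages, mid)

    def test_moments_recompute(self, rng):
        dists = [bin_pi_distribution(rng.uniform(3, 12, 50), organism_id=f"o{i}")
                 for i in range(10)]
        g = group_mean_sd_distribution(dists)
        mat = np.array([d.percentages for d in dists])
        assert np.allclose(g.mean_percentages, mat.mean(axis=0))
        assert np.allclose(g.sd_percentages, mat.std(axis=0, ddof=1))

    def test_bin_mismatch_rejected(self):
        d1 = bin_pi_distribution([5.0], bin_width=0.5, organism_id="a")
        d2 = bin_pi_distribution([5.0], bin_width=1.0, organism_id="b")
        with pytest.raises(ValidationError, match="bin mismatch"):
            group_mean_sd_distribution([d1, d2])


class TestPlantedChargeContrast:
    def test_acidic_plant_shifts_mean_pi_left(self):
        """Proteomes planted with elevated Asp/Glu usage sit at lower mean pI
        than proteomes planted with elevated Lys/Arg — the acidic-methanogen
        vs basic-sulphur-metaboliser contrast, on synthetic data."""
        acid, _ = simulate_proteome(0.5, n_proteins=25, seed=21,
                                    organism_id="acid", de_boost=2.0)
        base, _ = simulate_proteome(0.5, n_proteins=25, seed=22,
                                    organism_id="base", kr_boost=2.0)
        pi_acid = np.mean([isoelectric_point(r.sequence) for r in acid])
        pi_base = np.mean([isoelectric_point(r.sequence) for r in base])
        assert pi_acid < pi_base

    def test_acidic_basic_mixture_is_bimodal(self):
        rng = np.random.default_rng(9)
        res = list("ACFGHILMNPQSTVWY")  # neutral backbone pool
        seqs = []
        for _ in range(40):  # acidic proteins
            core = "".join(rng.choice(res, size=60))
            seqs.append(core + "D" * 10 + "E" * 10)
        for _ in range(40):  # basic proteins
            core = "".join(rng.choice(res, size=60))
            seqs.append(core + "K" * 10 + "R" * 10)
        d = bin_pi_distribution([isoelectric_point(s) for s in seqs])
        p = np.array(d.percentages)
        maxima = [i for i in range(1, len(p) - 1)
                  if p[i] > 0 and p[i] >= p[i - 1] and p[i] >= p[i + 1]
                  and (p[i] > p[i - 1] or p[i] > p[i + 1])]
        assert len(maxima) >= 2
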