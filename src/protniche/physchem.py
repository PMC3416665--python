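"""Per-protein physico-chemical indices and pI distribution profiles.

The isoelectric point is the root of the Henderson–Hasselbalch net-charge
function, found by bisection on [0, 14]; the charge model counts the free
termini plus the ionizable side chains (Asp, Glu, Cys, Tyr negative; His,
Lys, Arg positive) with a swappable pKa set (EMBOSS defaults). GRAVY uses
the Kyte–Doolittle hydropathy scale; the instability index uses the
Guruprasad dipeptide weights; the aliphatic index follows Ikai's formula
100*(X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu)) on mole fractions.

Ambiguity codes (B/Z/X/U) are excluded from every denominator, consistent
with :mod:`protniche.aa_usage`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import ProtParamData

from .io_core import Proteome, ValidationError
from .residues import RESIDUE_SET

# Ikai (1980) aliphatic-index coefficients: relative side-chain volumes of
# Val and Ile/Leu versus Ala.
ALIPHATIC_COEF_VAL = 2.9
ALIPHATIC_COEF_ILE_LEU = 3.9

KYTE_DOOLITTLE: Mapping[str, float] = ProtParamData.kd
DIPEPTIDE_INSTABILITY: Mapping[str, Mapping[str, float]] = ProtParamData.DIWV


@dataclass(frozen=True)
class PKaSet:
    """Ionizable-group pKa values. Defaults are the EMBOSS set."""

    nterm: float = 8.6
    cterm: float = 3.6
    side: Mapping[str, float] = field(default_factory=lambda: {
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
        "K": 10.8, "R": 12.5, "Y": 10.1,
    })
    name: str = "EMBOSS"

    def __post_init__(self):
        for v in (self.nterm, self.cterm, *self.side.values()):
            if not 0.0 < v < 14.0:
                raise ValidationError(f"pKa value {v} outside (0, 14)")


DEFAULT_PKA = PKaSet()

_POSITIVE_SIDE = ("H", "K", "R")
_NEGATIVE_SIDE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PhysChemRecord:
    protein_id: str
    gravy: float
    aromaticity: float
    aliphatic_index: float
    instability_index: float
    pi: float


@dataclass(frozen=True)
class PIDistribution:
    """Binned pI histogram for one organism, in percent of proteins."""

    organism_id: str
    bin_edges: tuple[float, ...]   # len = n_bins + 1, half-open [lo, hi)
    percentages: tuple[float, ...]

    def __post_init__(self):
        if abs(sum(self.percentages) - 100.0) > 1e-6:
            raise ValidationError(
                f"{self.organism_id}: bin percentages sum to {sum(self.percentages)}")


@dataclass(frozen=True)
class GroupDistribution:
    label: str
    bin_edges: tuple[float, ...]
    mean_percentages: tuple[float, ...]
    sd_percentages: tuple[float, ...]


def _countable(sequence: str) -> str:
    return "".join(c for c in sequence.upper() if c in RESIDUE_SET)


def net_charge_at_pH(sequence: str, pH: float,
                     pka_set: PKaSet = DEFAULT_PKA) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH.

    Positive groups (N-terminus, His, Lys, Arg) contribute
    n/(1 + 10^(pH - pKa)); negative groups (C-terminus, Asp, Glu, Cys, Tyr)
    contribute -n/(1 + 10^(pKa - pH)). Residues with no ionizable side chain
    (or unknown codes) contribute nothing.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    seq = sequence.upper()
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka_set.nterm))
    charge -= 1.0 / (1.0 + 10.0 ** (pka_set.cterm - pH))
    for aa in _POSITIVE_SIDE:
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - pka_set.side[aa]))
    for aa in _NEGATIVE_SIDE:
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka_set.side[aa] - pH))
    return charge


def isoelectric_point(sequence: str, pka_set: PKaSet = DEFAULT_PKA,
                      tol: float = 0.01, charge_tol: float = 1e-4,
                      max_iter: int = 200) -> float:
    """pH at which the modelled net charge is zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH under this model, so
    the bracket [0, 14] always contains exactly one root as long as the
    endpoint charges have opposite signs.
    """
    lo, hi = 0.0, 14.0
    c_lo = net_charge_at_pH(sequence, lo, pka_set)
    c_hi = net_charge_at_pH(sequence, hi, pka_set)
    if c_lo < 0 or c_hi > 0:
        raise ValidationError("charge function does not bracket a root on [0, 14]")
    mid = 7.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c_mid = net_charge_at_pH(sequence, mid, pka_set)
        if hi - lo < tol and abs(c_mid) <= charge_tol:
            break
        if c_mid > 0:
            lo = mid
        else:
            hi = mid
    return mid


def gravy(sequence: str) -> float:
    """Grand average of hydropathy (mean Kyte–Doolittle score)."""
    seq = _countable(sequence)
    if not seq:
        raise ValidationError("no countable residues for GRAVY")
    return sum(KYTE_DOOLITTLE[c] for c in seq) / len(seq)


def aromaticity(sequence: str) -> float:
    """Fraction of Phe + Tyr + Trp among countable residues."""
    seq = _countable(sequence)
    if not seq:
        raise ValidationError("no countable residues for aromaticity")
    return sum(seq.count(a) for a in "FYW") / len(seq)


def aliphatic_index(sequence: str) -> float:
    seq = _countable(sequence)
    if not seq:
        raise ValidationError("no countable residues for aliphatic index")
    n = len(seq)
    return 100.0 * (seq.count("A") / n
                    + ALIPHATIC_COEF_VAL * seq.count("V") / n
                    + ALIPHATIC_COEF_ILE_LEU * (seq.count("I") + seq.count("L")) / n)


def instability_index(sequence: str) -> float:
    """Guruprasad dipeptide instability index: (10/L) * sum of consecutive
    dipeptide weights. Dipeptides containing a non-standard code are skipped.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise ValidationError("instability index needs length >= 2")
    total = 0.0
    for a, b in zip(seq, seq[1:]):
        if a in DIPEPTIDE_INSTABILITY and b in DIPEPTIDE_INSTABILITY[a]:
            total += DIPEPTIDE_INSTABILITY[a][b]
    return 10.0 * total / len(seq)


def profile_proteome(proteome: Proteome,
                     pka_set: PKaSet = DEFAULT_PKA) -> pd.DataFrame:
    """All five indices for every protein of an organism, as a DataFrame
    indexed by protein_id."""
    rows = []
    for rec in proteome:
        rows.append({
            "protein_id": rec.id,
            "gravy": gravy(rec.sequence),
            "aromaticity": aromaticity(rec.sequence),
            "aliphatic_index": aliphatic_index(rec.sequence),
            "instability_index": instability_index(rec.sequence),
            "pi": isoelectric_point(rec.sequence, pka_set),
        })
    return pd.DataFrame(rows).set_index("protein_id")


def bin_pi_distribution(pi_values: Sequence[float], bin_width: float = 0.5,
                        lo: float = 2.0, hi: float = 14.0,
                        organism_id: str = "") -> PIDistribution:
    """Histogram pI values into half-open [edge, edge + width) bins over
    [lo, hi), as percentages. Out-of-range values are clamped into the end
    bins so the percentages always total 100."""
    values = np.asarray(list(pi_values), dtype=float)
    if values.size == 0:
        raise ValidationError("no pI values to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    idx = np.floor((values - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    pct = counts / values.size * 100.0
    # compensate float drift so the invariant holds exactly enough
    pct[-1] += 100.0 - pct.sum()
    return PIDistribution(organism_id=organism_id,
                          bin_edges=tuple(edges), percentages=tuple(pct))


def group_mean_sd_distribution(distributions: Sequence[PIDistribution],
                               label: str = "") -> GroupDistribution:
    """Per-bin mean and sample SD across organisms (Fig-style mean ± SD
    profile). A singleton group gets SD 0 in every bin."""
    if not distributions:
        raise ValidationError("no distributions given")
    edges = distributions[0].bin_edges
    for d in distributions[1:]:
        if d.bin_edges != edges:
            raise ValidationError(
                f"bin mismatch between {distributions[0].organism_id!r} "
                f"and {d.organism_id!r}")
    mat = np.array([d.percentages for d in distributions])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(distributions) > 1 else np.zeros(mat.shape[1])
    return GroupDistribution(label=label, bin_edges=edges,
                             mean_percentages=tuple(mean),
                             sd_percentages=tuple(sd))


def distribution_frame(dists: Sequence[PIDistribution]) -> pd.DataFrame:
    """Stack per-organism distributions into a bins x organisms table."""
    edges = dists[0].bin_edges
    index = [f"[{lo:.1f},{hi:.1f})" for lo, hi in zip(edges, edges[1:])]
    return pd.DataFrame({d.organism_id: d.percentages for d in dists}, index=index)
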