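"""Column conservation grading and hydrophobic-polar pattern resampling.

Conservation is scored per alignment column as one minus the normalised
Shannon entropy of the 20-amino-acid distribution (gaps excluded), then
binned into nine equal-width grades over [0, 1] with grade 9 the most
conserved.  This is a deliberately simple information-based grading, not a
phylogenetic rate model: it captures column variability, not evolutionary
rates corrected for tree structure.

The hydrophobic-polar (HP) pattern analysis subsamples single- and
double-domain lectin alignments without replacement and counts, per
replicate, how often a designated position pair (e.g. the residues aligned
to positions 5 and 91 of the garlic lectin) is polar-polar,
polar-hydrophobic or hydrophobic-hydrophobic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dca import ALPHABET, Alignment

__all__ = [
    "DEFAULT_HYDROPHOBIC",
    "ConservationProfile",
    "HPPatternResult",
    "conservation_grades",
    "classify_hp",
    "hp_pattern_analysis",
]

DEFAULT_HYDROPHOBIC = frozenset("AVLIMFWC")

N_GRADES = 9
_N_AA = 20


@dataclass
class ConservationProfile:
    scores: np.ndarray  # in [0, 1], nan for all-gap columns
    grades: np.ndarray  # 1..9, 0 for undefined columns
    gap_flag: np.ndarray  # True where the column is > 50 % gaps

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(len(self.scores)),
                "score": self.scores,
                "grade": self.grades,
                "gap_flag": self.gap_flag,
            }
        )


@dataclass
class HPPatternResult:
    """Per-replicate HP-pattern counts for one domain class."""

    counts: pd.DataFrame  # replicate, polar_polar, polar_hydrophobic, hydrophobic_hydrophobic
    subsample_size: int
    seed: int

    def fractions(self) -> pd.DataFrame:
        out = self.counts.copy()
        for col in ("polar_polar", "polar_hydrophobic", "hydrophobic_hydrophobic"):
            out[col] = out[col] / self.subsample_size
        return out


def conservation_grades(a: Alignment, gap_flag_fraction: float = 0.5) -> ConservationProfile:
    """Entropy-based conservation score and 9-grade binning per column.

    score = 1 - H/ln(20) over the amino-acid distribution of the column
    (gaps excluded); grade = equal-width bin of the score, 9 most conserved.
    All-gap columns get score nan and grade 0.
    """
    if a.M < 5:
        warnings.warn(f"only {a.M} sequences: conservation scores will be noisy")
    x = a.matrix
    m, length = x.shape
    scores = np.full(length, np.nan)
    grades = np.zeros(length, dtype=int)
    gap_frac = (x == 0).mean(axis=0)
    for j in range(length):
        col = x[:, j]
        col = col[col > 0]  # drop gaps
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=_N_AA + 1)[1:]
        p = counts[counts > 0] / col.size
        entropy = float(-(p * np.log(p)).sum())
        score = 1.0 - entropy / np.log(_N_AA)
        score = min(max(score, 0.0), 1.0)
        scores[j] = score
        grades[j] = min(N_GRADES, int(score * N_GRADES) + 1)
    return ConservationProfile(scores, grades, gap_frac > gap_flag_fraction)


def classify_hp(residue: str, hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC) -> str:
    """Binary polarity class of a one-letter amino-acid code.

    The default hydrophobic set is {A, V, L, I, M, F, W, C}; everything else
    is polar.  Gaps and nonstandard letters raise.
    """
    residue = residue.upper()
    if residue in ("-", "."):
        raise ValueError("cannot classify a gap")
    if residue not in ALPHABET or residue == ALPHABET[0]:
        raise ValueError(f"nonstandard residue letter {residue!r}")
    return "hydrophobic" if residue in hydrophobic_set else "polar"


def _pair_classes(
    a: Alignment,
    pos_pair: tuple[int, int],
    hydrophobic_set: frozenset[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Pattern class per sequence at the position pair; mask of usable rows.

    Rows with a gap at either position cannot be classified and are dropped
    from the sampling pool (with a warning when the gap fraction is high).
    """
    i, j = pos_pair
    length = a.L
    if not (0 <= i < length and 0 <= j < length):
        raise ValueError(f"position pair {pos_pair} outside alignment of length {length}")
    classes = np.full(a.M, -1, dtype=int)
    usable = np.ones(a.M, dtype=bool)
    for row in range(a.M):
        ci, cj = a.matrix[row, i], a.matrix[row, j]
        if ci == 0 or cj == 0:
            usable[row] = False
            continue
        hi = ALPHABET[ci] in hydrophobic_set
        hj = ALPHABET[cj] in hydrophobic_set
        classes[row] = int(hi) + int(hj)  # 0=PP, 1=PH, 2=HH
    gap_frac = 1.0 - usable.mean()
    if gap_frac > 0.5:
        warnings.warn(
            f"positions {pos_pair}: {gap_frac:.0%} of sequences have a gap there"
        )
    return classes, usable


def _sample_counts(
    classes: np.ndarray,
    pool: np.ndarray,
    n: int,
    reps: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    if n > pool.size:
        raise ValueError(
            f"subsample size {n} exceeds the {pool.size} gap-free sequences"
        )
    rows = []
    for rep in range(reps):
        chosen = rng.choice(pool, size=n, replace=False)
        c = classes[chosen]
        rows.append(
            {
                "replicate": rep,
                "polar_polar": int((c == 0).sum()),
                "polar_hydrophobic": int((c == 1).sum()),
                "hydrophobic_hydrophobic": int((c == 2).sum()),
            }
        )
    return pd.DataFrame(rows)


def hp_pattern_analysis(
    single: Alignment,
    double: Alignment,
    pos_pair: tuple[int, int],
    n_single: int = 31,
    n_double: int = 11,
    reps: int = 5,
    seed: int = 0,
    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC,
) -> tuple[HPPatternResult, HPPatternResult]:
    """HP interaction-pattern counts at a position pair, by domain class.

    Per replicate, ``n_single`` of the single-domain and ``n_double`` of the
    double-domain sequences are drawn without replacement and the residue
    pair of each drawn sequence is classified as polar-polar,
    polar-hydrophobic or hydrophobic-hydrophobic.  One seeded RNG stream
    drives all replicates, so results are reproducible bit for bit.
    """
    rng = np.random.default_rng(seed)
    out = []
    for aln, n in ((single, n_single), (double, n_double)):
        classes, usable = _pair_classes(aln, pos_pair, hydrophobic_set)
        pool = np.flatnonzero(usable)
        counts = _sample_counts(classes, pool, n, reps, rng)
        out.append(HPPatternResult(counts, subsample_size=n, seed=seed))
    return out[0], out[1]
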