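"""Mean-field direct coupling analysis (mfDCA) of protein alignments.

The pipeline follows the classic mean-field recipe: gap-rich columns are
removed, sequences are down-weighted by redundancy (>80 % identity),
pseudocount-regularised single and pair frequencies are computed over the
21-state alphabet (20 amino acids + gap), couplings are read off the
negative inverse of the empirical covariance matrix, and each column pair is
scored by direct information (DI) — the Kullback–Leibler divergence between
an isolated two-site model built from the inferred couplings and the
factorised background.

Frequencies use a bare pseudocount (default ``lambda = 0.5``):

    f_i(A)      = (lambda/21   + sum_a (1/m_a) d(A, A_i^a)) / (lambda + M_eff)
    f_ij(A, B)  = (lambda/21^2 + sum_a (1/m_a) d(A, A_i^a) d(B, A_j^a)) / (lambda + M_eff)

The covariance is assembled and inverted on a reduced q-1 = 20-state basis
with the gap as reference state; the full 21-state matrix is singular by
construction.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "Alignment",
    "SeqWeights",
    "FrequencyTables",
    "CouplingModel",
    "DirectInformation",
    "read_alignment",
    "filter_gap_columns",
    "sequence_weights",
    "frequencies",
    "couplings",
    "direct_information",
    "rank_pairs",
    "run_dca",
]

# state 0 is the gap; amino acids in alphabetical one-letter order
ALPHABET = "-ACDEFGHIKLMNPQRSTVWY"
Q = len(ALPHABET)  # 21
_CODE = {c: i for i, c in enumerate(ALPHABET)}


@dataclass
class Alignment:
    """M aligned sequences x L columns over the 21-state alphabet."""

    ids: list[str]
    matrix: np.ndarray  # (M, L) int8 codes into ALPHABET
    col_map: np.ndarray = field(default=None)  # original column index per column

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if self.matrix.min(initial=0) < 0 or self.matrix.max(initial=0) >= Q:
            raise ValueError("alignment codes outside the 21-state alphabet")
        if self.col_map is None:
            self.col_map = np.arange(self.matrix.shape[1])
        self.col_map = np.asarray(self.col_map, dtype=int)

    @property
    def M(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        return ["".join(ALPHABET[c] for c in row) for row in self.matrix]

    def subset_rows(self, rows) -> "Alignment":
        rows = np.asarray(rows, dtype=int)
        return Alignment([self.ids[i] for i in rows], self.matrix[rows], self.col_map)

    def subset_columns(self, cols) -> "Alignment":
        cols = np.asarray(cols, dtype=int)
        return Alignment(self.ids, self.matrix[:, cols], self.col_map[cols])


@dataclass
class SeqWeights:
    neighbor_counts: np.ndarray  # m_a, includes self
    identity_threshold: float

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.neighbor_counts

    @property
    def m_eff(self) -> float:
        return float(self.weights.sum())


@dataclass
class FrequencyTables:
    fi: np.ndarray  # (L, 21)
    fij: np.ndarray  # (L, L, 21, 21); diagonal blocks are delta(A,B) fi(A)
    pseudocount: float
    m_eff: float


@dataclass
class CouplingModel:
    eij: np.ndarray  # (L, L, 21, 21); gap is the zero reference state
    covariance: np.ndarray  # (L*(Q-1), L*(Q-1)) empirical covariance


@dataclass
class DirectInformation:
    di: np.ndarray  # (L, L), symmetric, zero diagonal
    col_map: np.ndarray


def read_alignment(fasta_text: str) -> Alignment:
    """Parse aligned FASTA; '.'/'-' become gaps, nonstandard letters too (warn)."""
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    ids = [r.id for r in records]
    rows = []
    nonstandard: set[str] = set()
    for r in records:
        row = []
        for ch in str(r.seq).upper():
            if ch in (".", "-"):
                row.append(0)
            elif ch in _CODE:
                row.append(_CODE[ch])
            else:
                nonstandard.add(ch)
                row.append(0)
        rows.append(row)
    if nonstandard:
        warnings.warn(
            f"nonstandard residue letters mapped to gap: {sorted(nonstandard)}"
        )
    return Alignment(ids, np.asarray(rows, dtype=np.int8))


def filter_gap_columns(a: Alignment, max_gap_fraction: float = 0.5) -> Alignment:
    """Drop columns whose gap fraction strictly exceeds ``max_gap_fraction``."""
    gap_frac = (a.matrix == 0).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    if keep.size == 0:
        raise ValueError("all columns exceed the gap-fraction threshold")
    return a.subset_columns(keep)


def sequence_weights(a: Alignment, identity_threshold: float = 0.8) -> SeqWeights:
    """Redundancy weights: ``m_a`` counts sequences >threshold identical to a.

    Identity is the fraction of matching columns with gaps counted as a
    regular state; ``m_a`` includes the sequence itself, and
    ``M_eff = sum_a 1/m_a``.
    """
    x = a.matrix
    m, length = x.shape
    counts = np.zeros(m, dtype=np.int64)
    block = max(1, int(2e7 // max(1, m * length)))
    for start in range(0, m, block):
        stop = min(m, start + block)
        ident = (x[start:stop, None, :] == x[None, :, :]).mean(axis=2)
        counts[start:stop] = (ident > identity_threshold).sum(axis=1)
    return SeqWeights(counts, identity_threshold)


def frequencies(a: Alignment, w: SeqWeights, pseudocount: float = 0.5) -> FrequencyTables:
    """Reweighted single and pair frequencies with a bare pseudocount.

    Diagonal blocks of ``fij`` follow the mean-field convention
    ``f_ii(A, B) = delta(A, B) f_i(A)``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0:
        warnings.warn("pseudocount 0: covariance inversion may be singular")
    x = a.matrix
    m, length = x.shape
    if len(w.neighbor_counts) != m:
        raise ValueError("weights computed on a different alignment")
    wt = w.weights
    m_eff = w.m_eff
    norm = pseudocount + m_eff

    onehot = np.zeros((m, length, Q))
    onehot[np.arange(m)[:, None], np.arange(length)[None, :], x] = 1.0

    fi = (pseudocount / Q + np.einsum("a,alq->lq", wt, onehot)) / norm
    fij = (
        pseudocount / Q**2
        + np.einsum("a,aiq,ajp->ijqp", wt, onehot, onehot)
    ) / norm
    # diagonal blocks: f_ii(A, B) = delta(A,B) f_i(A)
    for i in range(length):
        fij[i, i] = np.diag(fi[i])
    return FrequencyTables(fi, fij, pseudocount, m_eff)


def couplings(f: FrequencyTables) -> CouplingModel:
    """Mean-field couplings ``e_ij = -(C^emp)^{-1}`` on the 20-state basis.

    The empirical covariance ``C_ij(A, B) = f_ij(A, B) - f_i(A) f_j(B)`` is
    assembled over states 1..20 (gap = reference) and inverted; couplings of
    the reference state are implicitly zero.
    """
    fi, fij = f.fi, f.fij
    length = fi.shape[0]
    qr = Q - 1
    c = np.empty((length * qr, length * qr))
    for i in range(length):
        for j in range(length):
            block = fij[i, j, 1:, 1:] - np.outer(fi[i, 1:], fi[j, 1:])
            c[i * qr : (i + 1) * qr, j * qr : (j + 1) * qr] = block
    try:
        inv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular covariance matrix; use a pseudocount > 0"
        ) from exc
    eij = np.zeros((length, length, Q, Q))
    for i in range(length):
        for j in range(length):
            if i == j:
                continue
            eij[i, j, 1:, 1:] = -inv[i * qr : (i + 1) * qr, j * qr : (j + 1) * qr]
    return CouplingModel(eij, c)


def _fit_two_site(
    e: np.ndarray,
    fi: np.ndarray,
    fj: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> tuple[np.ndarray, float]:
    """Fit fields of the isolated two-site model by alternating updates.

    ``P^d(A, B) = exp(e(A, B) + h_i(A) + h_j(B)) / Z`` with marginals
    matched to ``fi, fj``.  Everything runs in the log domain (a Sinkhorn
    iteration on log-scaled factors), so arbitrarily large couplings — which
    the bare-pseudocount covariance inverse can produce on shallow
    alignments — cannot overflow.  Returns the fitted ``P^d`` and the
    residual marginal error.
    """
    from scipy.special import logsumexp

    with np.errstate(divide="ignore"):  # f = 0 legitimately maps to -inf
        log_fi = np.log(fi)
        log_fj = np.log(fj)
    # start from the independent-model fields; for weak couplings this is
    # already near the fixed point
    hi = log_fi.copy()
    hj = log_fj.copy()

    def log_p() -> np.ndarray:
        lp = e + hi[:, None] + hj[None, :]
        return lp - logsumexp(lp)

    lp = log_p()
    best = np.inf
    since_improved = 0
    for _ in range(max_iter):
        mi = np.exp(logsumexp(lp, axis=1))
        mj = np.exp(logsumexp(lp, axis=0))
        err = max(np.abs(mi - fi).max(), np.abs(mj - fj).max())
        if err < tol:
            return np.exp(lp), err
        # extreme couplings create float-level hard zeros in exp(e); the
        # iteration then stalls at its projection onto the feasible support
        if err < best * (1.0 - 1e-5):
            best, since_improved = err, 0
        else:
            since_improved += 1
            if since_improved >= 200:
                break
        hi += log_fi - logsumexp(lp, axis=1)
        lp = log_p()
        hj += log_fj - logsumexp(lp, axis=0)
        lp = log_p()
    mi = np.exp(logsumexp(lp, axis=1))
    mj = np.exp(logsumexp(lp, axis=0))
    return np.exp(lp), max(np.abs(mi - fi).max(), np.abs(mj - fj).max())


def direct_information(
    c: CouplingModel,
    f: FrequencyTables,
    tol: float = 1e-4,
    max_iter: int = 5000,
    col_map: np.ndarray | None = None,
) -> DirectInformation:
    """DI per column pair from the isolated two-site model.

    For each pair the fields are fitted so the two-site marginals equal the
    empirical single-column frequencies, then
    ``DI_ij = sum_AB P^d(A,B) ln(P^d(A,B) / (f_i(A) f_j(B)))`` (natural log,
    hence DI >= 0).
    """
    fi = f.fi
    length = fi.shape[0]
    di = np.zeros((length, length))
    stalled: list[tuple[int, int, float]] = []
    for i in range(length):
        for j in range(i + 1, length):
            p, err = _fit_two_site(c.eij[i, j], fi[i], fi[j], tol=tol, max_iter=max_iter)
            if err >= tol:
                if err < 100.0 * tol:
                    stalled.append((i, j, err))
                else:
                    raise RuntimeError(
                        f"two-site field fitting did not converge for pair ({i}, {j}): "
                        f"marginal error {err:.2e}"
                    )
            background = np.outer(fi[i], fi[j])
            mask = p > 0
            val = float(np.sum(p[mask] * np.log(p[mask] / background[mask])))
            di[i, j] = di[j, i] = max(val, 0.0)
    if stalled:
        worst = max(e for *_, e in stalled)
        warnings.warn(
            f"{len(stalled)} pair(s) hit degenerate couplings and stalled above "
            f"the marginal tolerance (worst residual {worst:.1e}); DI for these "
            "pairs is accurate only to that residual"
        )
    if col_map is None:
        col_map = np.arange(length)
    return DirectInformation(di, col_map=np.asarray(col_map, dtype=int))


def rank_pairs(
    d: DirectInformation,
    threshold: float = 0.8,
    min_separation: int = 2,
) -> pd.DataFrame:
    """Pairs sorted by DI descending, flagged where ``DI > threshold``.

    Pairs closer than ``min_separation`` columns (original numbering) are
    excluded from the flagged set but kept in the table.
    """
    length = d.di.shape[0]
    rows = []
    for i in range(length):
        for j in range(i + 1, length):
            oi, oj = int(d.col_map[i]), int(d.col_map[j])
            sep = abs(oj - oi)
            rows.append(
                {
                    "col_i": i,
                    "col_j": j,
                    "orig_i": oi,
                    "orig_j": oj,
                    "di": float(d.di[i, j]),
                    "flagged": bool(d.di[i, j] > threshold and sep >= min_separation),
                }
            )
    table = pd.DataFrame(rows).sort_values("di", ascending=False, ignore_index=True)
    return table


def run_dca(
    a: Alignment,
    pseudocount: float = 0.5,
    identity_threshold: float = 0.8,
    max_gap_fraction: float = 0.5,
    di_threshold: float = 0.8,
    min_separation: int = 2,
    columns: list[int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full mfDCA pipeline on an alignment; returns (DI table, run manifest).

    ``columns`` optionally restricts the analysis to a subset of original
    columns (e.g. the interface positions) before gap filtering.
    """
    if columns is not None:
        a = a.subset_columns(columns)
    filtered = filter_gap_columns(a, max_gap_fraction)
    w = sequence_weights(filtered, identity_threshold)
    f = frequencies(filtered, w, pseudocount)
    cm = couplings(f)
    d = direct_information(cm, f, col_map=filtered.col_map)
    table = rank_pairs(d, threshold=di_threshold, min_separation=min_separation)
    manifest = {
        "M": filtered.M,
        "L": filtered.L,
        "M_eff": w.m_eff,
        "pseudocount": pseudocount,
        "identity_threshold": identity_threshold,
        "max_gap_fraction": max_gap_fraction,
        "di_threshold": di_threshold,
    }
    return table, manifest
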