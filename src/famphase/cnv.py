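"""Per-exon copy-number estimation and the family co-segregation exact test.

Exon copy number is inferred from read depth: per-sample library-size
factors are divided out, each exon's across-sample median forms a baseline,
and the log2 depth/baseline ratio is converted to a z-score against a
robust (MAD-based) noise scale estimated within baseline-depth bins.  An
exon × sample call is gain/loss when its two-sided normal p-value falls
below alpha with the corresponding sign, mirroring the premise that exon
coverage varies linearly with true copy number.

Co-segregation of copy-number states with disease is scored per exon with
an exact conditional test on the 3×2 table

                affected   unaffected
    gain          n_ga        n_gu
    normal        n_na        n_nu
    loss          n_la        n_lu

with both margins fixed; the p-value sums the multivariate hypergeometric
probabilities of all tables no more probable than the observed one,
computed by full enumeration in exact rational arithmetic (the table space
is tiny for family-sized cohorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Pedigree

__all__ = [
    "ExonCoverageMatrix",
    "CnvCalls",
    "normalize_coverage",
    "call_exon_cnv",
    "coseg_contingency",
    "fisher_exact_3x2",
    "cnv_coseg_scan",
    "read_depth_tsv",
    "write_calls_tsv",
]

log = logging.getLogger(__name__)

STATE_LOSS, STATE_NORMAL, STATE_GAIN = -1, 0, 1


@dataclass
class ExonCoverageMatrix:
    """Per-exon mean read depth for a set of samples.

    ``exons``: DataFrame (chrom, start, end, name), 0-based half-open,
    unique and sorted.  ``depth``: float array (n_exons, n_samples) ≥ 0.
    """

    exons: pd.DataFrame
    depth: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.exons), len(self.samples)):
            raise ValueError("depth shape does not match exons × samples")
        if not np.isfinite(self.depth).all() or (self.depth < 0).any():
            raise ValueError("depths must be finite and non-negative")
        if self.exons["name"].duplicated().any():
            raise ValueError("exon names must be unique")
        self.exons = self.exons.reset_index(drop=True)


@dataclass
class CnvCalls:
    """Per exon × sample log2 ratios, p-values and 3-state calls."""

    exons: pd.DataFrame
    samples: list[str]
    log2_ratio: np.ndarray  # NaN where masked
    p_value: np.ndarray
    state: np.ndarray  # int8, -1 loss / 0 normal / +1 gain
    mask: np.ndarray  # True = exon excluded from calling
    baseline: np.ndarray
    alpha: float


def read_depth_tsv(path_or_buf) -> ExonCoverageMatrix:
    """Read a depth matrix TSV: exon_name, chrom, start, end, then samples."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"chrom": str})
    meta = ["exon_name", "chrom", "start", "end"]
    samples = [c for c in df.columns if c not in meta]
    exons = df[meta].rename(columns={"exon_name": "name"})[["chrom", "start", "end", "name"]]
    return ExonCoverageMatrix(exons, df[samples].to_numpy(dtype=float), samples)


def write_depth_tsv(cov: ExonCoverageMatrix, path_or_buf) -> None:
    out = cov.exons.rename(columns={"name": "exon_name"})[["exon_name", "chrom", "start", "end"]].copy()
    for j, s in enumerate(cov.samples):
        out[s] = cov.depth[:, j]
    out.to_csv(path_or_buf, sep="\t", index=False, float_format="%.3f")


def normalize_coverage(
    cov: ExonCoverageMatrix, min_baseline_depth: float = 10.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Library-size normalization and per-exon baseline.

    Returns ``(log2_ratio, baseline, mask)``.  Size factor per sample is
    its total exon depth divided by the across-sample mean total; the
    baseline per exon is the median of size-normalized depths; ratios are
    log2(normalized depth / baseline).  Exons with baseline below
    ``min_baseline_depth`` (including zero) are masked, never infinite.
    """
    if cov.depth.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    totals = cov.depth.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total depth")
    size_factors = totals / totals.mean()
    norm = cov.depth / size_factors[None, :]
    baseline = np.median(norm, axis=1)
    mask = baseline < min_baseline_depth
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.log2(norm / baseline[:, None])
    lr[mask] = np.nan
    return lr, baseline, mask


def _depth_bins(baseline: np.ndarray, unmasked: np.ndarray, n_bins: int, min_bin: int = 10) -> np.ndarray:
    """Equal-occupancy baseline-depth bins; bins below min_bin merge right."""
    idx = np.flatnonzero(unmasked)
    bin_of = np.full(len(baseline), -1, dtype=int)
    if len(idx) == 0:
        return bin_of
    n_bins = max(1, min(n_bins, len(idx)))
    order = np.argsort(baseline[idx], kind="stable")
    edges = np.array_split(idx[order], n_bins)
    merged: list[np.ndarray] = []
    carry: list[np.ndarray] = []
    for grp in edges:
        carry.append(grp)
        if sum(len(g) for g in carry) >= min_bin:
            merged.append(np.concatenate(carry))
            carry = []
    if carry:
        rest = np.concatenate(carry)
        if merged:
            merged[-1] = np.concatenate([merged[-1], rest])
        else:
            merged.append(rest)
    for b, grp in enumerate(merged):
        bin_of[grp] = b
    return bin_of


def call_exon_cnv(
    cov: ExonCoverageMatrix,
    alpha: float = 0.05,
    n_bins: int = 20,
    min_baseline_depth: float = 10.0,
) -> CnvCalls:
    """Call {gain, normal, loss} per exon × sample from depth ratios.

    Within equal-occupancy baseline-depth bins the log2 ratios are
    centered on the bin median and scaled by MAD × 1.4826; the two-sided
    normal tail probability of the resulting z-score is the call p-value.
    A call is gain iff p < alpha and the ratio is above the bin median,
    loss iff p < alpha and below; masked exons are never called.
    """
    lr, baseline, mask = normalize_coverage(cov, min_baseline_depth)
    bin_of = _depth_bins(baseline, ~mask, n_bins)
    z = np.full_like(lr, np.nan)
    for b in range(bin_of.max() + 1):
        rows = bin_of == b
        vals = lr[rows]
        center = np.nanmedian(vals)
        mad = np.nanmedian(np.abs(vals - center))
        scale = 1.4826 * mad
        if scale == 0:
            scale = np.nanstd(vals)  # degenerate bin: fall back to std
        if scale == 0:
            z[rows] = 0.0
        else:
            z[rows] = (lr[rows] - center) / scale
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(z))
    state = np.zeros(lr.shape, dtype=np.int8)
    sig = p < alpha
    state[sig & (z > 0)] = STATE_GAIN
    state[sig & (z < 0)] = STATE_LOSS
    state[mask] = STATE_NORMAL
    p[mask] = np.nan
    return CnvCalls(cov.exons, cov.samples, lr, p, state, mask, baseline, alpha)


def write_calls_tsv(calls: CnvCalls, path_or_buf) -> None:
    names = {STATE_LOSS: "loss", STATE_NORMAL: "normal", STATE_GAIN: "gain"}
    rows = []
    for i in np.flatnonzero(~calls.mask):
        exon = calls.exons.iloc[i]
        for j, s in enumerate(calls.samples):
            rows.append(
                (exon["name"], s, calls.log2_ratio[i, j], calls.p_value[i, j], names[int(calls.state[i, j])])
            )
    pd.DataFrame(rows, columns=["exon", "sample", "log2_ratio", "p", "state"]).to_csv(
        path_or_buf, sep="\t", index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# co-segregation exact test
# ---------------------------------------------------------------------------

def coseg_contingency(
    states: np.ndarray,
    samples: list[str],
    ped: Pedigree,
    groups: dict[str, str] | None = None,
) -> np.ndarray:
    """3×2 contingency of one exon's states by affection group.

    Rows are (gain, normal, loss); columns (affected, unaffected).  By
    default the column of a sample is its pedigree affection; ``groups``
    may remap samples to arbitrary two-group labels ("affected"/
    "unaffected" keys) to test other partitions.  Samples with unknown
    affection are excluded with a warning.
    """
    table = np.zeros((3, 2), dtype=np.int64)
    row = {STATE_GAIN: 0, STATE_NORMAL: 1, STATE_LOSS: 2}
    for s, st in zip(samples, states):
        grp = groups[s] if groups is not None else ped[s].affection
        if grp == "affected":
            col = 0
        elif grp == "unaffected":
            col = 1
        else:
            log.warning("sample %s has unknown affection; excluded from contingency", s)
            continue
        table[row[int(st)], col] += 1
    return table


@lru_cache(maxsize=100_000)
def _fisher_3x2_cached(cells: tuple[int, ...]) -> Fraction:
    table = np.array(cells, dtype=np.int64).reshape(3, 2)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    if n == 0:
        return Fraction(1)
    denom = comb(n, int(cols[0]))

    def prob(a0: int, a1: int, a2: int) -> Fraction:
        return Fraction(
            comb(int(rows[0]), a0) * comb(int(rows[1]), a1) * comb(int(rows[2]), a2), denom
        )

    obs = prob(int(table[0, 0]), int(table[1, 0]), int(table[2, 0]))
    total = Fraction(0)
    c0 = int(cols[0])
    for a0 in range(min(int(rows[0]), c0) + 1):
        for a1 in range(min(int(rows[1]), c0 - a0) + 1):
            a2 = c0 - a0 - a1
            if a2 < 0 or a2 > rows[2]:
                continue
            pr = prob(a0, a1, a2)
            if pr <= obs:
                total += pr
    return total


def fisher_exact_3x2(table: np.ndarray, *, as_fraction: bool = False) -> float | Fraction:
    """Two-sided exact conditional test on a 3×2 table, both margins fixed.

    p = sum of multivariate hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's.  Computed by full enumeration in exact rational arithmetic, so
    probability ties are handled exactly.  A zero-total table yields p = 1.
    """
    table = np.asarray(table)
    if table.shape != (3, 2):
        raise ValueError("expected a 3×2 table")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    p = _fisher_3x2_cached(tuple(int(x) for x in table.ravel()))
    return p if as_fraction else float(p)


def cnv_coseg_scan(
    calls: CnvCalls,
    ped: Pedigree,
    alpha: float = 0.05,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-exon exact co-segregation scan over unmasked exons.

    Returns a track (exon, chrom, start, end, p, minus_log10_p,
    significant) sorted by position; masked exons are absent.
    """
    rows = []
    for i in np.flatnonzero(~calls.mask):
        table = coseg_contingency(calls.state[i], calls.samples, ped, groups)
        p = fisher_exact_3x2(table)
        exon = calls.exons.iloc[i]
        rows.append((exon["name"], exon["chrom"], exon["start"], exon["end"], p))
    track = pd.DataFrame(rows, columns=["exon", "chrom", "start", "end", "p"])
    with np.errstate(divide="ignore"):
        track["minus_log10_p"] = -np.log10(track["p"])
    track["significant"] = track["p"] < alpha
    return track.sort_values(["chrom", "start"]).reset_index(drop=True)
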