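"""Exact single-point parametric linkage on pedigrees.

The disease model is the classical parametric one: a biallelic disease locus
with allele frequency ``q``, penetrance vector ``(f0, f1, f2)`` giving
P(affected | i copies of the disease allele), and a recombination fraction
``theta`` between the disease locus and the marker under test.  The LOD
score of a marker is

    LOD = log10 L(theta) - log10 L(theta = 1/2)

where L is the full-pedigree likelihood summed over all joint two-locus
ordered-haplotype configurations consistent with the observed marker
dosages: founder haplotypes carry Hardy–Weinberg / linkage-equilibrium
priors, each parent→child transmission carries a recombination-aware
haplotype probability, and each member with known affection carries a
penetrance factor.

The likelihood is evaluated by Elston–Stewart peeling, implemented as
variable elimination over the 16-state ordered two-locus genotype space in
reverse-topological order (children peeled before parents), which on
loop-free pedigrees reproduces the classical nuclear-family peeling with
factors never larger than a few genotype axes.  Factors are rescaled at
every elimination step so 13-member pedigrees with q = 1e-5 do not
underflow.  The peeler is batched: a whole panel's markers are reduced to
their unique (dosage-pattern, allele-frequency) classes and peeled in one
vectorized pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import MISSING, GenotypePanel, MarkerGenotypes
from .pedigree import Pedigree

__all__ = [
    "DiseaseModel",
    "QCParams",
    "HotSpot",
    "pedigree_log_likelihood",
    "lod_single_point",
    "lod_scan",
    "detect_hotspots",
]

log = logging.getLogger(__name__)

LN10 = np.log(10.0)

# --- two-locus state space -------------------------------------------------
# haplotype h = 2*d + m  (d = disease allele, m = marker alt allele)
# ordered genotype g = 4*h_pat + 4? no: g = 4*h_pat + h_mat, g in 0..15
HAP_D = np.array([0, 0, 1, 1])
HAP_M = np.array([0, 1, 0, 1])
G_HP = np.repeat(np.arange(4), 4)
G_HM = np.tile(np.arange(4), 4)
G_DCOUNT = HAP_D[G_HP] + HAP_D[G_HM]
G_MCOUNT = HAP_M[G_HP] + HAP_M[G_HM]

# --- single-locus state space (used for the factorized theta=1/2 null) ----
A1_P = np.repeat(np.arange(2), 2)  # paternal allele of ordered genotype
A1_M = np.tile(np.arange(2), 2)
G1_COUNT = A1_P + A1_M


def transmission_16x4(theta: float) -> np.ndarray:
    """P(transmit haplotype h | ordered parental two-locus genotype g).

    The parent picks a starting strand uniformly; with probability theta a
    crossover swaps the marker allele onto the other strand.
    """
    T = np.zeros((16, 4))
    for g in range(16):
        strands = (
            (HAP_D[G_HP[g]], HAP_M[G_HP[g]], HAP_M[G_HM[g]]),
            (HAP_D[G_HM[g]], HAP_M[G_HM[g]], HAP_M[G_HP[g]]),
        )
        for h in range(4):
            p = 0.0
            for d_s, m_same, m_other in strands:
                if HAP_D[h] == d_s:
                    p += 0.5 * ((1 - theta) * (HAP_M[h] == m_same) + theta * (HAP_M[h] == m_other))
            T[g, h] = p
    return T


def transmission_4x2() -> np.ndarray:
    """Single-locus Mendelian transmission P(allele a | ordered genotype g)."""
    T = np.zeros((4, 2))
    for g in range(4):
        for a in range(2):
            T[g, a] = 0.5 * (int(a == A1_P[g]) + int(a == A1_M[g]))
    return T


@dataclass(frozen=True)
class DiseaseModel:
    """Parametric disease model: penetrances, allele frequency, theta.

    Defaults are the fully penetrant autosomal-dominant model
    (f0, f1, f2) = (0, 1, 1) with disease allele frequency 1e-5 and
    complete linkage (theta = 0) as the test hypothesis.
    """

    penetrance: tuple[float, float, float] = (0.0, 1.0, 1.0)
    disease_allele_freq: float = 1e-5
    theta: float = 0.0

    def __post_init__(self) -> None:
        if len(self.penetrance) != 3 or not all(0.0 <= f <= 1.0 for f in self.penetrance):
            raise ValueError("penetrance must be three probabilities (f0, f1, f2)")
        if not (0.0 < self.disease_allele_freq < 1.0):
            raise ValueError("disease_allele_freq must lie in (0, 1)")
        _check_theta(self.theta)


def _check_theta(theta: float) -> None:
    if not (0.0 <= theta <= 0.5):
        raise ValueError(f"theta must lie in [0, 0.5], got {theta}")


@dataclass(frozen=True)
class QCParams:
    """Genotype-level QC for sequencing-derived marker panels."""

    min_depth: int = 10
    min_gq: int = 30
    autosomes_only: bool = True
    strict: bool = False  # True: require depth > min and gq > min (exclusive)


@dataclass
class HotSpot:
    """Cluster of above-threshold markers on one chromosome."""

    chrom: str
    start: int  # 1-based position of first member marker
    end: int  # 1-based position of last member marker (inclusive)
    marker_ids: list[str]
    max_lod: float

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# generic batched variable elimination
# ---------------------------------------------------------------------------

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _peel_order(ped: Pedigree) -> list[str]:
    """Elimination order: children before parents, smallest factor first."""
    varsets: list[set[str]] = []
    for ind in ped:
        if ind.is_founder:
            varsets.append({ind.id})
        else:
            varsets.append({ind.id, ind.father_id, ind.mother_id})
    remaining = set(ped.ids)
    children = {i: {c.id for c in ped.children_of(i)} for i in ped.ids}
    order: list[str] = []
    while remaining:
        cands = [i for i in remaining if not (children[i] & remaining)]
        costs = {}
        for c in cands:
            union: set[str] = set()
            for vs in varsets:
                if c in vs:
                    union |= vs
            costs[c] = len(union)
        pick = min(cands, key=lambda c: (costs[c], c))
        merged: set[str] = set()
        varsets = [vs for vs in varsets if pick not in vs or merged.update(vs) or False]
        merged.discard(pick)
        if merged:
            varsets.append(merged)
        remaining.discard(pick)
        order.append(pick)
    return order


def _eliminate(
    factors: list[tuple[tuple[str, ...], np.ndarray]],
    order: list[str],
    batch: int,
    n_states: int,
) -> np.ndarray:
    """Sum out variables in ``order``; return log of the scalar remainder.

    Each factor is (vars, array); arrays with ndim == len(vars) are shared
    across the batch, arrays with one extra leading axis are per-batch.
    Every new factor is rescaled by its per-batch maximum to avoid
    underflow; zeros (impossible configurations) yield -inf log-likelihood.
    """
    factors = list(factors)
    log_scale = np.zeros(batch)
    with np.errstate(divide="ignore", invalid="ignore"):
        for v in order:
            touching = [f for f in factors if v in f[0]]
            factors = [f for f in factors if v not in f[0]]
            union: list[str] = []
            for fvars, _ in touching:
                for u in fvars:
                    if u not in union:
                        union.append(u)
            letter = {u: _LETTERS[k] for k, u in enumerate(union)}
            out_vars = tuple(u for u in union if u != v)
            subs_in = []
            arrs = []
            for fvars, arr in touching:
                subs_in.append("..." + "".join(letter[u] for u in fvars))
                arrs.append(arr)
            expr = ",".join(subs_in) + "->..." + "".join(letter[u] for u in out_vars)
            new = np.einsum(expr, *arrs, optimize=True)
            batched = new.ndim > len(out_vars)
            state_axes = tuple(range(1 if batched else 0, new.ndim))
            m = new.max(axis=state_axes) if state_axes else new
            if not batched:
                m = np.asarray(m, dtype=float)
            safe = np.where(m > 0, m, 1.0)
            new = new / safe.reshape(safe.shape + (1,) * len(out_vars)) if out_vars else new / safe
            log_scale = log_scale + np.log(np.where(m > 0, m, 0.0))
            factors.append((out_vars, new))
        # remaining factors are scalar (possibly per-batch)
        rem = np.ones(batch)
        for _, arr in factors:
            rem = rem * arr
        return np.log(np.where(rem > 0, rem, 0.0)) + log_scale


# ---------------------------------------------------------------------------
# two-locus likelihood
# ---------------------------------------------------------------------------

def _penetrance_vector(model: DiseaseModel, affection: str, counts: np.ndarray) -> np.ndarray:
    f = np.asarray(model.penetrance)
    if affection == "affected":
        return f[counts]
    if affection == "unaffected":
        return 1.0 - f[counts]
    return np.ones(len(counts))


def _two_locus_loglik_batch(
    ped: Pedigree,
    dosage: np.ndarray,  # (B, n_members) aligned to ped.individuals, -1 missing
    freq: np.ndarray,  # (B,) marker alt-allele frequency
    model: DiseaseModel,
    theta: float,
    order: list[str] | None = None,
) -> np.ndarray:
    B = dosage.shape[0]
    q = model.disease_allele_freq
    T = transmission_16x4(theta)
    # trans[g_c, g_fa, g_mo] = T[g_fa, hp(g_c)] * T[g_mo, hm(g_c)]
    trans = T[:, G_HP].T[:, :, None] * T[:, G_HM].T[:, None, :]
    qvec = np.array([1.0 - q, q])
    ph_d = qvec[HAP_D]  # (4,)
    factors: list[tuple[tuple[str, ...], np.ndarray]] = []
    for j, ind in enumerate(ped.individuals):
        ev = np.broadcast_to(_penetrance_vector(model, ind.affection, G_DCOUNT), (B, 16)).copy()
        d = dosage[:, j]
        obs = d != MISSING
        if obs.any():
            ind_mask = (G_MCOUNT[None, :] == d[:, None]) | ~obs[:, None]
            ev *= ind_mask
        if ind.is_founder:
            pm = np.stack([1.0 - freq, freq], axis=1)  # (B, 2)
            ph = ph_d[None, :] * pm[:, HAP_M]  # (B, 4)
            ev *= ph[:, G_HP] * ph[:, G_HM]
            factors.append(((ind.id,), ev))
        else:
            factors.append(((ind.id,), ev))
            factors.append(((ind.id, ind.father_id, ind.mother_id), trans))
    return _eliminate(factors, order or _peel_order(ped), B, 16)


def _single_locus_loglik_batch(
    ped: Pedigree,
    freq: np.ndarray,  # (B,)
    evidence: list[np.ndarray],  # per member, (B, 4) or (4,) over ordered genotypes
    order: list[str] | None = None,
) -> np.ndarray:
    B = len(freq)
    T = transmission_4x2()
    trans = T[:, A1_P].T[:, :, None] * T[:, A1_M].T[:, None, :]  # (4,4,4)
    factors: list[tuple[tuple[str, ...], np.ndarray]] = []
    for j, ind in enumerate(ped.individuals):
        ev = np.array(evidence[j], dtype=float)
        if ev.ndim == 1:
            ev = np.broadcast_to(ev, (B, 4)).copy()
        if ind.is_founder:
            pa = np.stack([1.0 - freq, freq], axis=1)  # (B, 2)
            ev = ev * (pa[:, A1_P] * pa[:, A1_M])
            factors.append(((ind.id,), ev))
        else:
            factors.append(((ind.id,), ev))
            factors.append(((ind.id, ind.father_id, ind.mother_id), trans))
    return _eliminate(factors, order or _peel_order(ped), B, 4)


def _disease_only_loglik(ped: Pedigree, model: DiseaseModel) -> float:
    q = model.disease_allele_freq
    ev = [_penetrance_vector(model, ind.affection, G1_COUNT) for ind in ped.individuals]
    return float(_single_locus_loglik_batch(ped, np.array([q]), ev)[0])


def _marker_only_loglik_batch(
    ped: Pedigree, dosage: np.ndarray, freq: np.ndarray, order: list[str] | None = None
) -> np.ndarray:
    ev = []
    for j in range(dosage.shape[1]):
        d = dosage[:, j]
        mask = (G1_COUNT[None, :] == d[:, None]) | (d[:, None] == MISSING)
        ev.append(mask.astype(float))
    return _single_locus_loglik_batch(ped, freq, ev, order)


def _member_dosage_matrix(ped: Pedigree, panel: GenotypePanel) -> np.ndarray:
    """(n_markers, n_members) dosage matrix aligned to pedigree order."""
    out = np.full((len(panel), len(ped)), MISSING, dtype=np.int8)
    col = {s: j for j, s in enumerate(panel.subjects)}
    for k, ind in enumerate(ped.individuals):
        if ind.id in col:
            out[:, k] = panel.dosages[:, col[ind.id]]
    return out


def pedigree_log_likelihood(
    ped: Pedigree,
    marker: MarkerGenotypes,
    model: DiseaseModel,
    theta: float | None = None,
) -> float:
    """Natural-log two-locus pedigree likelihood of one marker's dosages.

    Raises if every pedigree member's dosage is missing (the marker carries
    no data) or theta is outside [0, 1/2].
    """
    theta = model.theta if theta is None else theta
    _check_theta(theta)
    dos = np.array(
        [[marker.dosages.get(ind.id, MISSING) for ind in ped.individuals]], dtype=np.int8
    )
    if (dos == MISSING).all():
        raise ValueError(f"marker {marker.marker_id}: all dosages missing; likelihood undefined")
    freq = np.array([marker.allele_freq_alt])
    return float(_two_locus_loglik_batch(ped, dos, freq, model, theta)[0])


def lod_single_point(ped: Pedigree, marker: MarkerGenotypes, model: DiseaseModel) -> float:
    """Single-point LOD: log10 L(model.theta) − log10 L(1/2)."""
    l1 = pedigree_log_likelihood(ped, marker, model, model.theta)
    l0 = pedigree_log_likelihood(ped, marker, model, 0.5)
    return (l1 - l0) / LN10


_SEX_CHROMS = {"X", "Y", "chrX", "chrY", "23", "24", "MT", "chrM"}


def apply_marker_qc(panel: GenotypePanel, qc: QCParams) -> GenotypePanel:
    """Drop markers failing genotype QC (WES panels) or autosome restriction."""
    keep = np.ones(len(panel), dtype=bool)
    if qc.autosomes_only:
        keep &= ~panel.markers["chrom"].astype(str).isin(_SEX_CHROMS).to_numpy()
    if panel.depth is not None and panel.gq is not None:
        genotyped = panel.dosages != MISSING
        if qc.strict:
            ok = (panel.depth > qc.min_depth) & (panel.gq > qc.min_gq)
        else:
            ok = (panel.depth >= qc.min_depth) & (panel.gq >= qc.min_gq)
        keep &= (ok | ~genotyped).all(axis=1)
    return panel.select_markers(np.flatnonzero(keep))


def lod_scan(
    ped: Pedigree,
    panel: GenotypePanel,
    model: DiseaseModel,
    qc: QCParams | None = None,
    chunk_size: int = 1500,
) -> pd.DataFrame:
    """Single-point LOD for every QC-passing marker of a panel.

    Returns a LOD track (marker_id, chrom, pos, lod) sorted by position.
    Markers are grouped by their unique (dosage pattern, allele frequency)
    class so each class is peeled once; the theta = 1/2 denominator uses
    the factorized form L = L(disease) × L(marker).  Markers whose dosage
    pattern is impossible under the pedigree (non-finite LOD, e.g. from
    genotyping errors) are excluded with a warning, as are markers with no
    genotyped member.
    """
    qc = qc or QCParams()
    panel = apply_marker_qc(panel, qc)
    if len(panel) == 0:
        log.warning("no markers survive QC; empty LOD track")
        return pd.DataFrame(columns=["marker_id", "chrom", "pos", "lod"])
    dosage = _member_dosage_matrix(ped, panel)
    freq = panel.markers["allele_freq_alt"].to_numpy(dtype=float)
    freq = np.where(np.isnan(freq), 0.5, freq)

    informative = (dosage != MISSING).any(axis=1)
    if not informative.all():
        log.warning("%d markers with no genotyped member excluded", int((~informative).sum()))

    key = np.column_stack([dosage, np.round(freq * 1e9).astype(np.int64)])
    _, uidx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    u_dos = dosage[uidx]
    u_freq = freq[uidx]
    B = len(uidx)

    order = _peel_order(ped)
    l1 = np.empty(B)
    for lo in range(0, B, chunk_size):
        hi = min(lo + chunk_size, B)
        l1[lo:hi] = _two_locus_loglik_batch(ped, u_dos[lo:hi], u_freq[lo:hi], model, model.theta, order)
    if model.theta == 0.5:
        l0 = l1.copy()
    else:
        l_dis = _disease_only_loglik(ped, model)
        l0 = np.empty(B)
        for lo in range(0, B, chunk_size):
            hi = min(lo + chunk_size, B)
            l0[lo:hi] = _marker_only_loglik_batch(ped, u_dos[lo:hi], u_freq[lo:hi], order)
        l0 = l0 + l_dis
    u_lod = (l1 - l0) / LN10

    lod = u_lod[inv]
    finite = np.isfinite(lod) & informative
    # L(theta)=0 markers are obligate recombinants under complete linkage
    # (LOD -inf); L(1/2)=0 markers are Mendelian-inconsistent outright.
    n_recomb = int((np.isneginf(lod) & np.isfinite(l0[inv])).sum())
    n_incons = int((~np.isfinite(lod) & informative).sum()) - n_recomb
    if n_recomb:
        log.info("%d obligate-recombinant markers (LOD -inf at theta=%.3g) excluded",
                 n_recomb, model.theta)
    if n_incons > 0:
        log.warning("%d Mendelian-inconsistent markers excluded", n_incons)
    track = panel.markers.loc[finite, ["marker_id", "chrom", "pos"]].copy()
    track["lod"] = lod[finite]
    return track.reset_index(drop=True)


def detect_hotspots(
    track: pd.DataFrame,
    threshold: float = 1.5,
    max_gap: int = 10_000_000,
    min_markers: int = 2,
) -> list[HotSpot]:
    """Greedily cluster above-threshold markers into hot spots.

    Consecutive markers on one chromosome with lod ≥ threshold separated by
    at most ``max_gap`` bp merge into one cluster; clusters with fewer than
    ``min_markers`` members are dropped (logged).
    """
    hits = track[track["lod"] >= threshold].sort_values(["chrom", "pos"])
    hotspots: list[HotSpot] = []
    for chrom, grp in hits.groupby("chrom", sort=False):
        cluster: list[tuple[str, int, float]] = []
        last_pos = None
        for _, row in grp.iterrows():
            if last_pos is not None and row["pos"] - last_pos > max_gap:
                _flush_cluster(cluster, chrom, min_markers, hotspots)
                cluster = []
            cluster.append((row["marker_id"], int(row["pos"]), float(row["lod"])))
            last_pos = row["pos"]
        _flush_cluster(cluster, chrom, min_markers, hotspots)
    return hotspots


def _flush_cluster(
    cluster: list[tuple[str, int, float]],
    chrom: str,
    min_markers: int,
    out: list[HotSpot],
) -> None:
    if not cluster:
        return
    if len(cluster) < min_markers:
        log.info(
            "isolated peak on %s at %d (lod %.2f) below min_markers=%d",
            chrom, cluster[0][1], max(c[2] for c in cluster), min_markers,
        )
        return
    out.append(
        HotSpot(
            chrom=str(chrom),
            start=cluster[0][1],
            end=cluster[-1][1],
            marker_ids=[c[0] for c in cluster],
            max_lod=max(c[2] for c in cluster),
        )
    )
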