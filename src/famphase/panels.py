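"""Biallelic genotype panels shared by the linkage and variant stages.

Genotypes are stored as alt-allele dosage in {0, 1, 2} with ``-1`` for
missing (VCF ``./.``).  A :class:`GenotypePanel` holds a marker table
(pandas) plus a dense dosage matrix (markers × subjects) and, for panels
sourced from sequencing, the per-genotype read depth (DP) and genotype
quality (GQ) used by QC filters.

Coordinate conventions: marker positions are 1-based (VCF native); exon
intervals elsewhere in the package are 0-based half-open (BED native).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .pedigree import Pedigree

__all__ = [
    "MISSING",
    "MarkerGenotypes",
    "GenotypePanel",
    "EmptyOverlapError",
    "read_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "mendelian_check",
    "harmonize_panels",
    "estimate_allele_freqs",
]

MISSING = -1

_MARKER_COLS = ["marker_id", "chrom", "pos", "ref", "alt", "allele_freq_alt"]


class EmptyOverlapError(ValueError):
    """Two panels share no subjects or no markers."""


@dataclass
class MarkerGenotypes:
    """Single biallelic marker: metadata plus per-subject dosages."""

    marker_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    dosages: dict[str, int]
    allele_freq_alt: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.allele_freq_alt < 1.0):
            raise ValueError("allele_freq_alt must lie strictly in (0, 1)")
        bad = {k: v for k, v in self.dosages.items() if v not in (0, 1, 2, MISSING)}
        if bad:
            raise ValueError(f"invalid dosages: {bad}")


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    s = chrom.astype(str).str.removeprefix("chr")
    num = pd.to_numeric(s, errors="coerce")
    # non-numeric chromosomes (X, Y, MT) sort after the autosomes
    return num.fillna(pd.Series(1000 + s.factorize()[0], index=s.index))


class GenotypePanel:
    """Dense biallelic genotype matrix over a fixed subject set.

    Parameters
    ----------
    markers
        DataFrame with columns marker_id, chrom, pos, ref, alt and
        (optionally) allele_freq_alt.
    dosages
        int array (n_markers, n_subjects), values in {0,1,2,-1}.
    subjects
        Subject ids, one per dosage column.
    platform
        "wes" or "array"; WES panels carry ``depth``/``gq`` matrices.
    """

    def __init__(
        self,
        markers: pd.DataFrame,
        dosages: np.ndarray,
        subjects: list[str],
        platform: str = "wes",
        depth: np.ndarray | None = None,
        gq: np.ndarray | None = None,
    ) -> None:
        if platform not in ("wes", "array"):
            raise ValueError(f"platform must be wes/array, got {platform!r}")
        markers = markers.copy()
        if "allele_freq_alt" not in markers:
            markers["allele_freq_alt"] = np.nan
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.shape != (len(markers), len(subjects)):
            raise ValueError("dosage matrix shape does not match markers × subjects")
        order = np.lexsort((markers["pos"].to_numpy(), _chrom_sort_key(markers["chrom"]).to_numpy()))
        self.markers = markers.iloc[order].reset_index(drop=True)
        self.dosages = dosages[order]
        self.subjects = list(subjects)
        self.platform = platform
        self.depth = None if depth is None else np.asarray(depth)[order]
        self.gq = None if gq is None else np.asarray(gq)[order]
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def marker(self, i: int) -> MarkerGenotypes:
        row = self.markers.iloc[i]
        af = row["allele_freq_alt"]
        return MarkerGenotypes(
            marker_id=row["marker_id"],
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            dosages={s: int(d) for s, d in zip(self.subjects, self.dosages[i])},
            allele_freq_alt=0.5 if np.isnan(af) else float(af),
        )

    def select_markers(self, idx: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            self.markers.iloc[idx].reset_index(drop=True),
            self.dosages[idx],
            self.subjects,
            self.platform,
            None if self.depth is None else self.depth[idx],
            None if self.gq is None else self.gq[idx],
        )

    def select_subjects(self, subjects: list[str]) -> "GenotypePanel":
        cols = [self.subjects.index(s) for s in subjects]
        return GenotypePanel(
            self.markers,
            self.dosages[:, cols],
            subjects,
            self.platform,
            None if self.depth is None else self.depth[:, cols],
            None if self.gq is None else self.gq[:, cols],
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypePanel:
    """Read a biallelic VCF (GT/DP/GQ) into a WES :class:`GenotypePanel`."""
    with pysam.VariantFile(path) as vf:
        subjects = list(vf.header.samples)
        rows, dos, dps, gqs = [], [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # multi-allelic markers are out of scope
            rows.append(
                (
                    rec.id or f"{rec.chrom}:{rec.pos}",
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alts[0],
                )
            )
            d_row, dp_row, gq_row = [], [], []
            for s in subjects:
                call = rec.samples[s]
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    d_row.append(MISSING)
                else:
                    d_row.append(int(sum(gt)))
                dp_row.append(call.get("DP") if call.get("DP") is not None else 0)
                gq_row.append(call.get("GQ") if call.get("GQ") is not None else 0)
            dos.append(d_row)
            dps.append(dp_row)
            gqs.append(gq_row)
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "ref", "alt"])
    return GenotypePanel(
        markers,
        np.array(dos, dtype=np.int8),
        subjects,
        platform="wes",
        depth=np.array(dps, dtype=np.int32),
        gq=np.array(gqs, dtype=np.int32),
    )


def read_genotype_tsv(path_or_buf, platform: str = "array") -> GenotypePanel:
    """Read a microarray-style dosage TSV.

    Layout: marker_id, chrom, pos, ref, alt[, allele_freq_alt], then one
    dosage column per subject ("NA" or -1 = missing).
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"chrom": str})
    meta_cols = [c for c in _MARKER_COLS if c in df.columns]
    subject_cols = [c for c in df.columns if c not in meta_cols]
    dos = df[subject_cols].fillna(MISSING).to_numpy(dtype=np.int8)
    return GenotypePanel(df[meta_cols], dos, subject_cols, platform=platform)


def write_genotype_tsv(panel: GenotypePanel, path_or_buf) -> None:
    out = panel.markers[[c for c in _MARKER_COLS if c in panel.markers]].copy()
    for j, s in enumerate(panel.subjects):
        out[s] = panel.dosages[:, j]
    out.to_csv(path_or_buf, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pedigree-aware operations
# ---------------------------------------------------------------------------

# possible transmitted allele sets per parental dosage (index -1 = missing)
_TRANSMIT = {0: {0}, 1: {0, 1}, 2: {1}, MISSING: {0, 1}}


def mendelian_check(ped: Pedigree, panel: GenotypePanel) -> list[tuple[str, str]]:
    """List (marker_id, child_id) pairs with impossible transmissions.

    A child is flagged when its dosage cannot be formed from one allele of
    each parent given the parental dosages; missing dosages (child or
    parent) are treated as uninformative and never flagged.
    """
    extra = set(panel.subjects) - set(ped.ids)
    if extra:
        raise ValueError(f"panel subjects not in pedigree: {sorted(extra)}")
    col = {s: j for j, s in enumerate(panel.subjects)}
    violations: list[tuple[str, str]] = []
    ids = panel.markers["marker_id"].to_numpy()
    for ind in ped.nonfounders:
        if ind.id not in col:
            continue
        child = panel.dosages[:, col[ind.id]].astype(np.int32)
        fa = (
            panel.dosages[:, col[ind.father_id]].astype(np.int32)
            if ind.father_id in col
            else np.full(len(panel), MISSING)
        )
        mo = (
            panel.dosages[:, col[ind.mother_id]].astype(np.int32)
            if ind.mother_id in col
            else np.full(len(panel), MISSING)
        )
        # possible child dosages: {a+b : a ∈ transmit(fa), b ∈ transmit(mo)}
        lo = (fa == 2).astype(np.int32) + (mo == 2).astype(np.int32)
        hi = 2 - (fa == 0).astype(np.int32) - (mo == 0).astype(np.int32)
        bad = (child != MISSING) & ((child < lo) | (child > hi))
        for i in np.flatnonzero(bad):
            violations.append((ids[i], ind.id))
    return violations


def harmonize_panels(a: GenotypePanel, b: GenotypePanel) -> tuple[GenotypePanel, GenotypePanel]:
    """Restrict two panels to shared subjects and shared (chrom,pos,alleles).

    Markers present in both panels with ref/alt swapped are recoded in ``b``
    (dosage d → 2−d, alleles flipped) before matching, so strand-consistent
    allele flips do not drop markers.
    """
    subjects = [s for s in a.subjects if s in set(b.subjects)]
    if not subjects:
        raise EmptyOverlapError("no shared subjects")

    def key(df: pd.DataFrame) -> pd.Index:
        return pd.Index(
            df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["ref"] + ":" + df["alt"]
        )

    akey = key(a.markers)
    # recode allele-swapped markers in b
    b_m = b.markers.copy()
    swapped_key = pd.Index(
        b_m["chrom"].astype(str) + ":" + b_m["pos"].astype(str) + ":" + b_m["alt"] + ":" + b_m["ref"]
    )
    to_swap = swapped_key.isin(akey) & ~key(b_m).isin(akey)
    b_dos = b.dosages.copy()
    if to_swap.any():
        warnings.warn(f"recoding {int(to_swap.sum())} allele-swapped markers", stacklevel=2)
        idx = np.flatnonzero(to_swap)
        obs = b_dos[idx] != MISSING
        b_dos[idx] = np.where(obs, 2 - b_dos[idx], MISSING)
        b_m.loc[to_swap, ["ref", "alt"]] = b_m.loc[to_swap, ["alt", "ref"]].to_numpy()
        if "allele_freq_alt" in b_m:
            b_m.loc[to_swap, "allele_freq_alt"] = 1.0 - b_m.loc[to_swap, "allele_freq_alt"]
    b2 = GenotypePanel(b_m, b_dos, b.subjects, b.platform, b.depth, b.gq)

    bkey = key(b2.markers)
    shared = akey.intersection(bkey)
    if len(shared) == 0:
        raise EmptyOverlapError("no shared markers")
    a_idx = np.flatnonzero(akey.isin(shared))
    b_idx = np.flatnonzero(bkey.isin(shared))
    return (
        a.select_markers(a_idx).select_subjects(subjects),
        b2.select_markers(b_idx).select_subjects(subjects),
    )


def estimate_allele_freqs(
    panel: GenotypePanel,
    ped: Pedigree,
    *,
    min_founders: int = 2,
    default: float = 0.5,
    pseudocount: float = 0.5,
) -> GenotypePanel:
    """Fill allele_freq_alt from genotyped founders.

    Per marker: if ≥ ``min_founders`` founders have a non-missing dosage,
    the frequency is the pseudocount-smoothed founder alt fraction
    (Σd + c) / (2n + 2c); otherwise ``default``.  Smoothing keeps the
    estimate strictly inside (0, 1) as the likelihood requires.
    """
    founder_cols = [panel.subjects.index(f.id) for f in ped.founders if f.id in panel.subjects]
    markers = panel.markers.copy()
    if founder_cols:
        d = panel.dosages[:, founder_cols].astype(np.float64)
        obs = d != MISSING
        n = obs.sum(axis=1)
        alt = np.where(obs, d, 0.0).sum(axis=1)
        freq = (alt + pseudocount) / (2 * n + 2 * pseudocount)
        markers["allele_freq_alt"] = np.where(n >= min_founders, freq, default)
    else:
        markers["allele_freq_alt"] = default
    return GenotypePanel(markers, panel.dosages, panel.subjects, panel.platform, panel.depth, panel.gq)
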