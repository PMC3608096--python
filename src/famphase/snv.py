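"""Variant QC, novelty/effect filtering and co-segregation candidate selection.

A :class:`VariantSet` couples per-variant annotation (gene, coding effect,
HGVS strings, known-variant id, population frequency — consumed from an
annotation sidecar, never computed here) with per-sample genotype dosage,
read depth and genotype quality from a multi-sample VCF.  Filters are pure
(each returns a new subset), so survivor sets are always subsets of their
inputs and the funnel order can be audited or permuted.

The decisive filter for a fully penetrant dominant family design is
co-segregation: keep variants carried (dosage ≥ 1) by every sequenced
affected member and absent (dosage 0) from every sequenced unaffected
member.  The final candidates may additionally be intersected with linkage
hot spots, each candidate annotated with the containing hot spot's maximum
LOD.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .linkage import HotSpot
from .panels import MISSING, _chrom_sort_key, read_vcf
from .pedigree import Pedigree

__all__ = [
    "VariantSet",
    "EFFECT_KEEP",
    "load_variants",
    "qc_filter",
    "known_filter",
    "effect_filter",
    "segregation_filter",
    "hotspot_intersect",
    "render_candidate_table",
]

log = logging.getLogger(__name__)

EFFECT_KEEP = {"nonsynonymous", "stopgain", "stoploss", "frameshift", "nonframeshift", "splicing"}

ANNOTATION_COLS = [
    "chrom", "pos", "ref", "alt", "gene", "effect", "hgvs_c", "hgvs_p", "known_id", "pop_freq",
]

_SEX_CHROMS = {"X", "Y", "chrX", "chrY", "23", "24", "MT", "chrM"}


class VariantSet:
    """Annotated variants plus per-sample (dosage, DP, GQ) matrices."""

    def __init__(
        self,
        table: pd.DataFrame,
        samples: list[str],
        dosage: np.ndarray,
        depth: np.ndarray,
        gq: np.ndarray,
    ) -> None:
        n = len(table)
        for name, arr in (("dosage", dosage), ("depth", depth), ("gq", gq)):
            if arr.shape != (n, len(samples)):
                raise ValueError(f"{name} matrix shape mismatch")
        self.table = table.reset_index(drop=True)
        self.samples = list(samples)
        self.dosage = np.asarray(dosage)
        self.depth = np.asarray(depth)
        self.gq = np.asarray(gq)

    def __len__(self) -> int:
        return len(self.table)

    def select(self, keep: np.ndarray) -> "VariantSet":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return VariantSet(
            self.table.iloc[idx], self.samples, self.dosage[idx], self.depth[idx], self.gq[idx]
        )

    def keys(self) -> set[tuple]:
        return set(zip(self.table["chrom"], self.table["pos"], self.table["ref"], self.table["alt"]))


def load_variants(vcf_path: str, annotation_path: str) -> VariantSet:
    """Join a VCF with its annotation sidecar keyed by (chrom, pos, ref, alt).

    Variants without an annotation row get null annotation fields (and an
    "other" effect is NOT assumed: effect stays missing and effect_filter
    will drop them with a warning).
    """
    panel = read_vcf(vcf_path)
    ann = pd.read_csv(
        annotation_path, sep="\t", dtype={"chrom": str, "known_id": str}, na_values=["-", ""]
    )
    missing = [c for c in ANNOTATION_COLS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation sidecar missing columns: {missing}")
    meta = panel.markers.drop(columns=["allele_freq_alt"]).merge(
        ann, on=["chrom", "pos", "ref", "alt"], how="left"
    )
    if "type" not in meta:
        indel = (meta["ref"].str.len() != 1) | (meta["alt"].str.len() != 1)
        meta["type"] = np.where(indel, "indel", "snv")
    return VariantSet(meta, panel.subjects, panel.dosages, panel.depth, panel.gq)


def qc_filter(
    vs: VariantSet,
    min_depth: int = 10,
    min_gq: int = 30,
    autosomes_only: bool = False,
    strict: bool = False,
) -> VariantSet:
    """Keep variants where every sample's genotype passes depth/GQ QC.

    Default boundary keeps genotypes with depth ≥ min_depth and
    GQ ≥ min_gq; ``strict`` switches to exclusive (>) comparisons.
    ``autosomes_only`` additionally drops sex-chromosome variants.
    """
    if strict:
        ok = (vs.depth > min_depth) & (vs.gq > min_gq)
    else:
        ok = (vs.depth >= min_depth) & (vs.gq >= min_gq)
    keep = ok.all(axis=1)
    if autosomes_only:
        keep &= ~vs.table["chrom"].astype(str).isin(_SEX_CHROMS).to_numpy()
    return vs.select(keep)


def known_filter(vs: VariantSet, mode: str = "annotate_only", max_freq: float = 0.01) -> VariantSet:
    """Database-novelty filter.

    ``drop_known`` removes variants carrying a known-variant id or a
    population frequency above ``max_freq``; ``annotate_only`` (default)
    passes everything through, leaving the annotation available downstream
    — the decisive family filter is co-segregation, and known common
    variants can and do survive it.
    """
    if mode == "annotate_only":
        return vs.select(np.ones(len(vs), dtype=bool))
    if mode != "drop_known":
        raise ValueError(f"mode must be drop_known/annotate_only, got {mode!r}")
    has_id = vs.table["known_id"].notna().to_numpy()
    freq = vs.table["pop_freq"].to_numpy(dtype=float)
    common = np.nan_to_num(freq, nan=0.0) > max_freq
    return vs.select(~(has_id | common))


def effect_filter(vs: VariantSet) -> VariantSet:
    """Keep amino-acid-changing / splicing variants; drop synonymous, other
    and unannotated (warned)."""
    eff = vs.table["effect"]
    n_missing = int(eff.isna().sum())
    if n_missing:
        log.warning("%d variants without effect annotation dropped", n_missing)
    return vs.select(eff.isin(EFFECT_KEEP).to_numpy())


def segregation_filter(vs: VariantSet, ped: Pedigree) -> VariantSet:
    """Keep variants co-segregating with affection under a dominant model.

    Requires dosage ≥ 1 in every sequenced affected member and dosage 0 in
    every sequenced unaffected member; a missing dosage in either group
    fails the variant (conservative).  Members with unknown affection are
    not constrained.
    """
    aff_cols = [vs.samples.index(i.id) for i in ped.members(affection="affected", sequenced=True)
                if i.id in vs.samples]
    un_cols = [vs.samples.index(i.id) for i in ped.members(affection="unaffected", sequenced=True)
               if i.id in vs.samples]
    keep = np.ones(len(vs), dtype=bool)
    if aff_cols:
        keep &= (vs.dosage[:, aff_cols] >= 1).all(axis=1)  # MISSING (-1) fails
    if un_cols:
        keep &= (vs.dosage[:, un_cols] == 0).all(axis=1)
    return vs.select(keep)


def hotspot_intersect(
    vs: VariantSet, hotspots: list[HotSpot], enabled: bool = True
) -> VariantSet:
    """Restrict to variants inside linkage hot spots (inclusive, 1-based).

    Each surviving variant's table gains a ``max_lod`` column from its
    containing hot spot.  With ``enabled=False`` all variants pass and
    max_lod is attached where available (NaN elsewhere), mirroring the
    independently reportable unintersected track.
    """
    max_lod = np.full(len(vs), np.nan)
    inside = np.zeros(len(vs), dtype=bool)
    chroms = vs.table["chrom"].astype(str).to_numpy()
    pos = vs.table["pos"].to_numpy()
    for hs in hotspots:
        hit = (chroms == hs.chrom) & (pos >= hs.start) & (pos <= hs.end)
        inside |= hit
        max_lod[hit] = np.fmax(np.nan_to_num(max_lod[hit], nan=-np.inf), hs.max_lod)
    out = vs.select(inside if enabled else np.ones(len(vs), dtype=bool))
    out.table = out.table.assign(max_lod=max_lod[inside] if enabled else max_lod)
    if enabled and not hotspots:
        log.warning("hot-spot intersection enabled with no hot spots; candidate table is empty")
    return out


def render_candidate_table(vs: VariantSet) -> str:
    """Format the candidate list with the six classical report columns."""
    header = ["Gene", "Chr", "Nucleotide variation", "Amino acid variation",
              "Frequency in 1,000 genome", "dbSNP135"]
    lines = ["\t".join(header)]
    tab = vs.table.assign(_ck=_chrom_sort_key(vs.table["chrom"])).sort_values(["_ck", "pos"])
    for _, row in tab.iterrows():
        freq = row.get("pop_freq")
        lines.append(
            "\t".join(
                [
                    str(row.get("gene") or "-"),
                    str(row["chrom"]),
                    str(row.get("hgvs_c") or "-"),
                    str(row.get("hgvs_p") or "-"),
                    "-" if freq is None or (isinstance(freq, float) and np.isnan(freq)) else f"{freq:g}",
                    str(row.get("known_id")) if pd.notna(row.get("known_id")) else "-",
                ]
            )
        )
    return "\n".join(lines) + "\n"
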