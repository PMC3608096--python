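"""End-to-end orchestration of the multiphasic analysis.

Stage order is fixed: exon CNV calling + co-segregation scan, then
single-point linkage over the exome SNV markers (optionally validated on a
second, microarray-style panel), then the SNV filter funnel whose final
candidates are intersected with the linkage hot spots.  Every stage writes
its artifact into the output directory and the run report records the
funnel counts, so the narrowing from all variants to the candidate list is
auditable.  The analysis is deterministic given its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import cnv as cnvmod
from . import snv as snvmod
from .cnv import CnvCalls, ExonCoverageMatrix, call_exon_cnv, cnv_coseg_scan, read_depth_tsv
from .linkage import DiseaseModel, HotSpot, QCParams, detect_hotspots, lod_scan
from .panels import GenotypePanel, estimate_allele_freqs, mendelian_check, read_genotype_tsv
from .pedigree import Pedigree, parse_pedigree
from .snv import (
    VariantSet,
    effect_filter,
    hotspot_intersect,
    known_filter,
    load_variants,
    qc_filter,
    render_candidate_table,
    segregation_filter,
)

__all__ = ["StageParams", "RunConfig", "RunReport", "run_all", "analyze", "compare_tracks"]

log = logging.getLogger(__name__)


class StageParams(BaseModel):
    """All tunable analysis parameters with their documented defaults."""

    theta: float = 0.0
    penetrance: tuple[float, float, float] = (0.0, 1.0, 1.0)
    disease_freq: float = 1e-5
    min_depth: int = 10
    min_gq: int = 30
    qc_strict: bool = False
    autosomes_only: bool = True
    cnv_alpha: float = 0.05
    cnv_bins: int = 20
    min_baseline_depth: float = 10.0
    scan_alpha: float = 0.05
    lod_threshold: float = 1.5
    max_gap: int = 10_000_000
    min_markers: int = 2
    known_mode: str = "annotate_only"
    known_max_freq: float = 0.01
    intersect_hotspots: bool = True

    def disease_model(self) -> DiseaseModel:
        return DiseaseModel(self.penetrance, self.disease_freq, self.theta)

    def qc(self) -> QCParams:
        return QCParams(self.min_depth, self.min_gq, self.autosomes_only, self.qc_strict)


class RunConfig(BaseModel):
    """File locations plus stage parameters for one pipeline run."""

    ped: Path
    vcf: Path
    annotation: Path
    bed: Path | None = None
    depth: Path | None = None
    array: Path | None = None
    outdir: Path = Path("famphase_out")
    params: StageParams = Field(default_factory=StageParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validated(self) -> "RunConfig":
        for name in ("ped", "vcf", "annotation", "bed", "depth", "array"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        return self


@dataclass
class RunReport:
    """Per-stage counts and result tables of one pipeline run."""

    funnel: dict[str, int]
    hotspots: list[HotSpot]
    track: pd.DataFrame
    cnv_scan: pd.DataFrame | None
    candidates: VariantSet
    array_concordance: pd.DataFrame | None = None
    n_cnv_calls: int = 0
    n_mendel_excluded: int = 0

    def check_funnel(self) -> None:
        counts = list(self.funnel.values())
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError(f"filter funnel not monotone: {self.funnel}")

    def render(self) -> str:
        lines = ["# famphase run report", "", "## Variant filter funnel"]
        for k, v in self.funnel.items():
            lines.append(f"{k}\t{v}")
        lines += ["", "## Linkage hot spots (chrom, start, end, n_markers, max_lod)"]
        for hs in self.hotspots:
            lines.append(f"{hs.chrom}\t{hs.start}\t{hs.end}\t{hs.n_markers}\t{hs.max_lod:.4f}")
        if self.cnv_scan is not None and len(self.cnv_scan):
            best = self.cnv_scan.nsmallest(1, "p").iloc[0]
            lines += ["", "## CNV co-segregation scan",
                      f"exons_tested\t{len(self.cnv_scan)}",
                      f"significant\t{int(self.cnv_scan['significant'].sum())}",
                      f"min_p\t{best['p']:.6g}\t{best['exon']}"]
        lines += ["", "## Candidates", render_candidate_table(self.candidates).rstrip()]
        return "\n".join(lines) + "\n"


def _variant_panel(vs: VariantSet) -> GenotypePanel:
    return GenotypePanel(
        vs.table[["marker_id", "chrom", "pos", "ref", "alt"]],
        vs.dosage,
        vs.samples,
        platform="wes",
        depth=vs.depth,
        gq=vs.gq,
    )


def analyze(
    ped: Pedigree,
    variants: VariantSet,
    coverage: ExonCoverageMatrix | None,
    params: StageParams,
    array_panel: GenotypePanel | None = None,
) -> tuple[RunReport, CnvCalls | None]:
    """Run all stages in memory and return the report plus CNV calls."""
    # --- stage 1: CNV ---------------------------------------------------
    calls = cnv_scan = None
    if coverage is not None:
        try:
            calls = call_exon_cnv(coverage, params.cnv_alpha, params.cnv_bins, params.min_baseline_depth)
            cnv_scan = cnv_coseg_scan(calls, ped, params.cnv_alpha)
        except Exception as e:
            raise RuntimeError("stage 'cnv' failed") from e

    # --- stage 2: linkage -----------------------------------------------
    try:
        panel = _variant_panel(variants)
        viol = mendelian_check(ped, panel)
        bad_ids = {m for m, _ in viol}
        if bad_ids:
            log.info("excluding %d markers with Mendelian violations from linkage", len(bad_ids))
            keep = ~panel.markers["marker_id"].isin(bad_ids).to_numpy()
            panel = panel.select_markers(np.flatnonzero(keep))
        panel = estimate_allele_freqs(panel, ped)
        model = params.disease_model()
        track = lod_scan(ped, panel, model, params.qc())
        hotspots = detect_hotspots(track, params.lod_threshold, params.max_gap, params.min_markers)
    except Exception as e:
        raise RuntimeError("stage 'linkage' failed") from e

    # --- stage 3: SNV funnel ---------------------------------------------
    try:
        funnel = {"total": len(variants)}
        vs = qc_filter(variants, params.min_depth, params.min_gq, params.autosomes_only, params.qc_strict)
        funnel["qc"] = len(vs)
        vs = known_filter(vs, params.known_mode, params.known_max_freq)
        funnel["known"] = len(vs)
        vs = effect_filter(vs)
        funnel["effect"] = len(vs)
        vs = segregation_filter(vs, ped)
        funnel["segregation"] = len(vs)
        vs = hotspot_intersect(vs, hotspots, enabled=params.intersect_hotspots)
        funnel["hotspot"] = len(vs)
    except Exception as e:
        raise RuntimeError("stage 'snv' failed") from e

    concordance = None
    if array_panel is not None:
        try:
            apanel = estimate_allele_freqs(array_panel, ped)
            atrack = lod_scan(ped, apanel, model, params.qc())
            concordance = compare_tracks(track, atrack, hotspots, params.lod_threshold)
        except Exception as e:
            raise RuntimeError("stage 'array-validation' failed") from e

    report = RunReport(
        funnel=funnel,
        hotspots=hotspots,
        track=track,
        cnv_scan=cnv_scan,
        candidates=vs,
        array_concordance=concordance,
        n_cnv_calls=0 if calls is None else int((calls.state != 0).sum()),
        n_mendel_excluded=len(bad_ids),
    )
    report.check_funnel()
    return report, calls


def run_all(config: RunConfig) -> RunReport:
    """File-based pipeline: read inputs, analyze, write stage artifacts."""
    config = config.validated()
    p = config.params
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    variants = load_variants(str(config.vcf), str(config.annotation))
    ped = parse_pedigree(Path(config.ped).read_text(), sequenced_ids=variants.samples)
    coverage = read_depth_tsv(config.depth) if config.depth else None
    array_panel = read_genotype_tsv(config.array) if config.array else None

    report, calls = analyze(ped, variants, coverage, p, array_panel)

    if calls is not None:
        cnvmod.write_calls_tsv(calls, outdir / "cnv_calls.tsv")
        report.cnv_scan.to_csv(outdir / "cnv_scan.tsv", sep="\t", index=False, float_format="%.6g")
        sig = report.cnv_scan[report.cnv_scan["significant"]]
        sig[["chrom", "start", "end", "exon"]].to_csv(
            outdir / "cnv_significant.bed", sep="\t", index=False, header=False
        )
    report.track.to_csv(outdir / "lod_track.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        [(h.chrom, h.start, h.end, h.n_markers, h.max_lod) for h in report.hotspots],
        columns=["chrom", "start", "end", "n_markers", "max_lod"],
    ).to_csv(outdir / "hotspots.tsv", sep="\t", index=False, float_format="%.6g")
    cand = report.candidates.table.copy()
    cand.to_csv(outdir / "candidates.tsv", sep="\t", index=False, na_rep="-", float_format="%.6g")
    (outdir / "candidates.txt").write_text(render_candidate_table(report.candidates))
    pd.DataFrame(list(report.funnel.items()), columns=["stage", "n"]).to_csv(
        outdir / "funnel.tsv", sep="\t", index=False
    )
    if report.array_concordance is not None:
        report.array_concordance.to_csv(
            outdir / "array_concordance.tsv", sep="\t", index=False, float_format="%.6g"
        )
    (outdir / "report.txt").write_text(report.render())
    return report


def compare_tracks(
    track_a: pd.DataFrame,
    track_b: pd.DataFrame,
    hotspots: list[HotSpot] | None = None,
    threshold: float = 1.5,
    max_gap: int = 10_000_000,
    min_markers: int = 2,
) -> pd.DataFrame:
    """Concordance of hot spots between two LOD tracks.

    For each hot spot of track A (detected with the given parameters if
    not supplied), reports the maximum LOD among track-B markers inside
    the interval and whether the hot spot is recovered (that maximum
    reaches the threshold).  The ``recovered`` column's mean is the
    recovery fraction; an empty B track recovers nothing (warned).
    """
    if hotspots is None:
        hotspots = detect_hotspots(track_a, threshold, max_gap, min_markers)
    if len(track_b) == 0:
        log.warning("validation track is empty; no hot spots recovered")
    rows = []
    for hs in hotspots:
        sel = track_b[
            (track_b["chrom"].astype(str) == hs.chrom)
            & (track_b["pos"] >= hs.start)
            & (track_b["pos"] <= hs.end)
        ]
        best = float(sel["lod"].max()) if len(sel) else float("-inf")
        rows.append((hs.chrom, hs.start, hs.end, hs.max_lod, best, best >= threshold))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "max_lod_a", "max_lod_b", "recovered"]
    )
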