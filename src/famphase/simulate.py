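"""Synthetic family-exome generator.

Produces, from a single seed, every input the analysis consumes — pedigree
(PED), multi-sample variant calls (VCF with GT/DP/GQ), an annotation
sidecar, exon intervals (BED), a per-exon depth matrix and an optional
microarray-style panel — together with the ground truth needed to verify
recovery.

The generative model mirrors the assumptions of the analysis itself:

* **Gene dropping.**  Founder haplotypes are drawn per marker from a
  uniform allele-frequency distribution under Hardy–Weinberg equilibrium
  and linkage equilibrium; each child receives one haplotype per parent
  with free recombination between markers.  Exactly one causal variant is
  placed on one haplotype of the (single) affected founder and transmitted
  so that carrier status coincides with affection — the fully penetrant
  autosomal-dominant regime.  All other markers segregate independently of
  disease.
* **Depth.**  Exon read counts are negative binomial with mean
  proportional to mean depth × library-size factor × capture-efficiency
  factor × copy number / 2, so depth scales linearly with copy number.
  Per-genotype DP at called variant sites is 10 + NB(mean−10): genotype
  calls presuppose minimally adequate coverage, unlike raw target bases.
* **Errors.**  Genotypes are perturbed at ``genotype_error_rate``;
  erroneous genotypes carry degraded GQ (uniform 5–40) so quality filters
  are exercised, correct genotypes carry GQ 99.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .cnv import ExonCoverageMatrix, write_depth_tsv
from .panels import MISSING, GenotypePanel, write_genotype_tsv
from .pedigree import Individual, Pedigree, write_pedigree
from .snv import VariantSet

__all__ = [
    "AUTOSOME_LENGTHS",
    "CnvEvent",
    "SimConfig",
    "SimTruth",
    "SimData",
    "default_family",
    "gene_drop",
    "simulate_coverage",
    "simulate_family",
    "emit_fixture",
]

# hg19-scale autosome lengths (bp), rounded
AUTOSOME_LENGTHS = {
    "chr1": 249_250_000, "chr2": 243_199_000, "chr3": 198_022_000, "chr4": 191_154_000,
    "chr5": 180_915_000, "chr6": 171_115_000, "chr7": 159_138_000, "chr8": 146_364_000,
    "chr9": 141_213_000, "chr10": 135_534_000, "chr11": 135_006_000, "chr12": 133_851_000,
    "chr13": 115_169_000, "chr14": 107_349_000, "chr15": 102_531_000, "chr16": 90_354_000,
    "chr17": 81_195_000, "chr18": 78_077_000, "chr19": 59_128_000, "chr20": 63_025_000,
    "chr21": 48_129_000, "chr22": 51_304_000,
}


def default_family() -> Pedigree:
    """13-member, 3-generation family: 8 sequenced (4 affected incl. the
    founder, 4 unaffected), one member with equivocal status, and a second
    founder couple whose children extend the array panel."""
    seq = {"I-1", "I-2", "II-1", "II-2", "II-3", "II-5", "II-7", "II-9"}
    inds = [
        Individual("I-1", None, None, "male", "affected"),
        Individual("I-2", None, None, "female", "unaffected"),
        Individual("II-1", "I-1", "I-2", "female", "unaffected"),
        Individual("II-2", "I-1", "I-2", "male", "affected"),
        Individual("II-3", "I-1", "I-2", "female", "affected"),
        Individual("II-4", None, None, "male", "unaffected"),
        Individual("II-5", "I-1", "I-2", "female", "affected"),
        Individual("II-6", "I-1", "I-2", "female", "unknown"),
        Individual("II-7", "I-1", "I-2", "male", "unaffected"),
        Individual("II-9", "I-1", "I-2", "female", "unaffected"),
        Individual("III-1", "II-4", "II-3", "male", "affected"),
        Individual("III-2", "II-4", "II-3", "female", "unaffected"),
        Individual("III-4", "II-4", "II-3", "male", "unaffected"),
    ]
    return Pedigree(inds, name="F1").with_sequenced(seq)


DEFAULT_ARRAY_SUBJECTS = [
    "I-1", "I-2", "II-1", "II-2", "II-3", "II-4", "II-5", "II-7", "II-9", "III-1", "III-4",
]


class CnvEvent(BaseModel):
    """One implanted copy-number event over a run of consecutive exons."""

    first_exon: int
    n_exons: int = 1
    carriers: list[str]
    copy_number: int

    @field_validator("copy_number")
    @classmethod
    def _cn(cls, v: int) -> int:
        if v not in (0, 1, 3, 4):
            raise ValueError("copy_number must be in {0, 1, 3, 4}")
        return v


def _default_cnv_events() -> list[CnvEvent]:
    # five distinct, non-co-segregating CNV loci: one shared locus with
    # reciprocal gain/loss carriers plus four scattered deletions/gains
    return [
        CnvEvent(first_exon=1000, n_exons=8, carriers=["II-9"], copy_number=3),
        CnvEvent(first_exon=1000, n_exons=8, carriers=["II-3", "II-7"], copy_number=1),
        CnvEvent(first_exon=2000, n_exons=4, carriers=["I-1", "II-3", "II-7", "II-9"], copy_number=1),
        CnvEvent(first_exon=3000, n_exons=3, carriers=["I-2", "II-7"], copy_number=1),
        CnvEvent(first_exon=3600, n_exons=2, carriers=["II-1"], copy_number=3),
        CnvEvent(first_exon=4200, n_exons=2, carriers=["I-2"], copy_number=3),
    ]


class SimConfig(BaseModel):
    """Study-condition parameters for the synthetic family exome."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    pedigree: Pedigree = Field(default_factory=default_family)
    n_markers: int = 18_000
    causal_chrom: str = "chr17"
    causal_pos: int = 79_000_000
    causal_gene: str = "GENE_C"
    freq_low: float = 0.05
    freq_high: float = 0.95
    mean_depth: float = 45.0
    variant_depth_dispersion: float = 30.0  # NB size for per-genotype DP − 10
    exon_depth_dispersion: float = 400.0  # NB size for per-exon read counts
    capture_sigma: float = 0.5  # lognormal sd of per-exon capture efficiency
    genotype_error_rate: float = 0.0
    cnv_events: list[CnvEvent] = Field(default_factory=_default_cnv_events)
    n_exons: int = 5_000
    exon_mean_length: float = 300.0
    indel_fraction: float = 0.02
    novel_fraction: float = 0.05
    array_subjects: list[str] = Field(default_factory=lambda: list(DEFAULT_ARRAY_SUBJECTS))
    array_marker_stride: int = 2
    seed: int = 0

    @field_validator("causal_chrom")
    @classmethod
    def _autosomal(cls, v: str) -> str:
        if v not in AUTOSOME_LENGTHS:
            raise ValueError(f"causal locus must be autosomal, got {v!r}")
        return v

    def validated(self) -> "SimConfig":
        ped = self.pedigree
        ids = set(ped.ids)
        for ev in self.cnv_events:
            if not set(ev.carriers) <= ids:
                raise ValueError(f"CNV carriers not in pedigree: {ev.carriers}")
            if ev.first_exon + ev.n_exons > self.n_exons:
                raise ValueError("CNV event exceeds exon count")
        if not set(self.array_subjects) <= ids:
            raise ValueError("array subjects must be pedigree members")
        aff_founders = [i for i in ped.founders if i.affection == "affected"]
        if len(aff_founders) != 1:
            raise ValueError(
                "full-penetrance dominant gene drop needs exactly one affected founder"
            )
        carrier_ok = {aff_founders[0].id}
        # reachability: every affected non-founder needs a potential carrier parent
        changed = True
        while changed:
            changed = False
            for ind in ped.nonfounders:
                if ind.id in carrier_ok:
                    continue
                if ind.father_id in carrier_ok or ind.mother_id in carrier_ok:
                    if ind.affection in ("affected", "unknown"):
                        carrier_ok.add(ind.id)
                        changed = True
        bad = [i.id for i in ped if i.affection == "affected" and i.id not in carrier_ok]
        if bad:
            raise ValueError(f"affected members unreachable by the causal allele: {bad}")
        return self


@dataclass
class SimTruth:
    """Ground truth of one simulated family exome."""

    causal_marker_id: str
    causal_chrom: str
    causal_pos: int
    carriers: list[str]
    haplotypes: dict[str, np.ndarray]  # id -> (2, M) alleles, row 0 = paternal
    true_dosage: np.ndarray  # (M, n_members) pre-error dosages
    error_mask: np.ndarray  # (M, n_members) True where a genotype error was injected
    true_freq: np.ndarray  # (M,) simulated population allele frequencies
    copy_number: np.ndarray | None = None  # (E, n_samples) once coverage simulated
    exon_names: list[str] | None = None

    def summary(self) -> dict:
        out = {
            "causal_marker_id": self.causal_marker_id,
            "causal_chrom": self.causal_chrom,
            "causal_pos": self.causal_pos,
            "carriers": self.carriers,
            "n_causal_variants": 1,
            "n_errors": int(self.error_mask.sum()),
        }
        if self.copy_number is not None and self.exon_names is not None:
            rows = np.flatnonzero((self.copy_number != 2).any(axis=1))
            out["cnv_exons"] = [self.exon_names[i] for i in rows]
        return out


@dataclass
class SimData:
    """Everything one simulated family provides, in memory."""

    config: SimConfig
    pedigree: Pedigree
    panel_all: GenotypePanel  # all pedigree members, dosage only
    wes_panel: GenotypePanel  # sequenced members with DP/GQ
    variants: VariantSet  # WES variants joined with annotation
    annotation: pd.DataFrame
    coverage: ExonCoverageMatrix
    array_panel: GenotypePanel
    truth: SimTruth


def _topological_nonfounders(ped: Pedigree) -> list[Individual]:
    done = {i.id for i in ped.founders}
    out: list[Individual] = []
    todo = list(ped.nonfounders)
    while todo:
        progress = [i for i in todo if i.father_id in done and i.mother_id in done]
        if not progress:
            raise ValueError("pedigree is not well-founded")
        for ind in progress:
            out.append(ind)
            done.add(ind.id)
        todo = [i for i in todo if i.id not in done]
    return out


def gene_drop(config: SimConfig, rng: np.random.Generator | None = None) -> tuple[GenotypePanel, SimTruth]:
    """Drop founder haplotypes through the pedigree.

    Returns a dosage panel over **all** pedigree members plus the truth
    record.  The causal variant occupies one marker at the configured
    locus, private to the affected founder's carrier haplotype, and is
    transmitted so that carriers and affected members coincide (members of
    unknown affection inherit it at random).
    """
    config = config.validated()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ped = config.pedigree
    M = config.n_markers

    chroms = list(AUTOSOME_LENGTHS)
    lens = np.array([AUTOSOME_LENGTHS[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=M - 1, p=lens / lens.sum())
    pos = (rng.random(M - 1) * lens[ci]).astype(np.int64) + 1
    # keep (chrom, pos) keys unique so the annotation join is one-to-one
    for _ in range(10):
        key = pd.MultiIndex.from_arrays([ci, pos])
        dup = key.duplicated() | ((np.array(chroms)[ci] == config.causal_chrom) & (pos == config.causal_pos))
        if not dup.any():
            break
        pos[dup] = (rng.random(int(dup.sum())) * lens[ci[dup]]).astype(np.int64) + 1
    chrom_arr = np.array([chroms[i] for i in ci] + [config.causal_chrom])
    pos = np.concatenate([pos, [config.causal_pos]])
    freq = rng.uniform(config.freq_low, config.freq_high, size=M)
    causal_idx = M - 1

    is_indel = rng.random(M) < config.indel_fraction
    is_indel[causal_idx] = False
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=M)]
    alt = np.array([bases[(list(bases).index(r) + int(k)) % 4] for r, k in zip(ref, rng.integers(1, 4, size=M))])
    ref = ref.astype(object)
    alt = alt.astype(object)
    for i in np.flatnonzero(is_indel):
        if rng.random() < 0.5:
            ref[i] = ref[i] + "".join(rng.choice(bases, size=int(rng.integers(1, 4))))
            alt[i] = ref[i][0]
        else:
            alt[i] = ref[i] + "".join(rng.choice(bases, size=int(rng.integers(1, 4))))

    aff_founder = next(i for i in ped.founders if i.affection == "affected")
    haplo: dict[str, np.ndarray] = {}
    for f in ped.founders:
        h = (rng.random((2, M)) < freq[None, :]).astype(np.int8)
        h[:, causal_idx] = 0
        haplo[f.id] = h
    haplo[aff_founder.id][0, causal_idx] = 1  # the causal haplotype

    for ind in _topological_nonfounders(ped):
        h = np.empty((2, M), dtype=np.int8)
        for row, pid in ((0, ind.father_id), (1, ind.mother_id)):
            parent = haplo[pid]
            choice = rng.integers(0, 2, size=M)
            carrier_strand = np.flatnonzero(parent[:, causal_idx] == 1)
            if len(carrier_strand):  # parent carries the causal allele
                if ind.affection == "affected":
                    choice[causal_idx] = carrier_strand[0]
                elif ind.affection == "unaffected":
                    choice[causal_idx] = 1 - carrier_strand[0]
            h[row] = parent[choice, np.arange(M)]
        haplo[ind.id] = h

    members = ped.ids
    dosage = np.stack([haplo[i].sum(axis=0) for i in members], axis=1).astype(np.int8)
    true_dosage = dosage.copy()

    err = np.zeros_like(dosage, dtype=bool)
    if config.genotype_error_rate > 0:
        err = rng.random(dosage.shape) < config.genotype_error_rate
        shift = rng.integers(1, 3, size=dosage.shape)
        dosage = np.where(err, (dosage + shift) % 3, dosage).astype(np.int8)

    marker_ids = np.array([f"mk{i:06d}" for i in range(M)], dtype=object)
    markers = pd.DataFrame(
        {"marker_id": marker_ids, "chrom": chrom_arr, "pos": pos, "ref": ref, "alt": alt}
    )
    panel = GenotypePanel(markers, dosage, members, platform="wes")
    # align truth arrays with the panel's (chrom, pos) sort order
    perm = panel.markers["marker_id"].str.removeprefix("mk").astype(int).to_numpy()
    carriers = [i for i in members if haplo[i][:, causal_idx].sum() > 0]
    truth = SimTruth(
        causal_marker_id=marker_ids[causal_idx],
        causal_chrom=config.causal_chrom,
        causal_pos=config.causal_pos,
        carriers=carriers,
        haplotypes={k: h[:, perm] for k, h in haplo.items()},
        true_dosage=true_dosage[perm],
        error_mask=err[perm],
        true_freq=freq[perm],
    )
    return panel, truth


def simulate_coverage(
    config: SimConfig, truth: SimTruth | None = None, rng: np.random.Generator | None = None
) -> ExonCoverageMatrix:
    """Simulate the per-exon mean-depth matrix for the sequenced samples.

    Exon read counts are NB(mean = mean_depth · L/100 · size factor ·
    capture factor · CN/2, size = exon_depth_dispersion); the depth entry
    is count × 100 / L.  Implanted CNV events set CN ≠ 2 for their
    carriers; all other exons have CN 2.  If ``truth`` is given it gains
    the per-exon true copy numbers.
    """
    config = config.validated()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    samples = [i.id for i in config.pedigree.members(sequenced=True)]
    E, S = config.n_exons, len(samples)

    chroms = list(AUTOSOME_LENGTHS)
    lens = np.array([AUTOSOME_LENGTHS[c] for c in chroms], dtype=float)
    ci = rng.choice(len(chroms), size=E, p=lens / lens.sum())
    start = (rng.random(E) * (lens[ci] - 2000)).astype(np.int64)
    length = np.clip(
        rng.lognormal(np.log(config.exon_mean_length * 0.9), 0.35, size=E), 120, 1500
    ).astype(np.int64)
    exons = pd.DataFrame(
        {"chrom": [chroms[i] for i in ci], "start": start, "end": start + length}
    ).sort_values(["chrom", "start"]).reset_index(drop=True)
    exons["name"] = [f"ex{i:05d}" for i in range(E)]
    length = (exons["end"] - exons["start"]).to_numpy()

    cn = np.full((E, S), 2, dtype=np.int8)
    scol = {s: j for j, s in enumerate(samples)}
    for ev in config.cnv_events:
        rows = slice(ev.first_exon, ev.first_exon + ev.n_exons)
        for c in ev.carriers:
            if c in scol:
                cn[rows, scol[c]] = ev.copy_number

    size_factor = rng.lognormal(0.0, 0.05, size=S)
    capture = rng.lognormal(0.0, config.capture_sigma, size=E)
    mean_reads = (
        config.mean_depth * (length / 100.0)[:, None] * capture[:, None]
        * size_factor[None, :] * (cn / 2.0)
    )
    disp = config.exon_depth_dispersion
    p_nb = disp / (disp + np.maximum(mean_reads, 1e-9))
    reads = rng.negative_binomial(disp, p_nb)
    reads[mean_reads == 0] = 0
    depth = reads * 100.0 / length[:, None]
    if truth is not None:
        truth.copy_number = cn
        truth.exon_names = list(exons["name"])
    return ExonCoverageMatrix(exons, depth, samples)


def simulate_family(config: SimConfig) -> SimData:
    """Run the full generator and assemble every stage input in memory."""
    config = config.validated()
    rng = np.random.default_rng(config.seed)
    ped = config.pedigree
    panel_all, truth = gene_drop(config, rng)
    coverage = simulate_coverage(config, truth, rng)

    seq_ids = [i.id for i in ped.members(sequenced=True)]
    wes = panel_all.select_subjects(seq_ids)
    M, S = wes.dosages.shape
    mu = max(config.mean_depth - 10.0, 1.0)
    disp = config.variant_depth_dispersion
    dp = (10 + rng.negative_binomial(disp, disp / (disp + mu), size=(M, S))).astype(np.int32)
    gq = np.full((M, S), 99, dtype=np.int32)
    # degraded quality where a genotype error was injected
    err_wes = pd.DataFrame(truth.error_mask, columns=panel_all.subjects)[seq_ids].to_numpy()
    gq = np.where(err_wes, rng.integers(5, 41, size=(M, S)), gq).astype(np.int32)
    wes = GenotypePanel(wes.markers, wes.dosages, wes.subjects, "wes", depth=dp, gq=gq)

    annotation = _make_annotation(config, wes, truth, rng)
    meta = wes.markers.drop(columns=["allele_freq_alt"]).merge(
        annotation, on=["chrom", "pos", "ref", "alt"], how="left"
    )
    indel = (meta["ref"].str.len() != 1) | (meta["alt"].str.len() != 1)
    meta["type"] = np.where(indel, "indel", "snv")
    variants = VariantSet(meta, wes.subjects, wes.dosages, dp, gq)

    idx = np.arange(0, len(panel_all), config.array_marker_stride)
    causal_row = np.flatnonzero(
        (panel_all.markers["marker_id"] == truth.causal_marker_id).to_numpy()
    )
    array_panel = panel_all.select_subjects(config.array_subjects).select_markers(
        np.union1d(idx, causal_row)
    )
    array_panel.platform = "array"
    return SimData(config, ped, panel_all, wes, variants, annotation, coverage, array_panel, truth)


def _make_annotation(
    config: SimConfig, wes: GenotypePanel, truth: SimTruth, rng: np.random.Generator
) -> pd.DataFrame:
    mk = wes.markers
    M = len(mk)
    causal = (mk["marker_id"] == truth.causal_marker_id).to_numpy()
    indel = (mk["ref"].str.len() != 1).to_numpy() | (mk["alt"].str.len() != 1).to_numpy()
    effect = np.where(
        rng.random(M) < 0.58, "synonymous", np.where(rng.random(M) < 0.95, "nonsynonymous", "splicing")
    ).astype(object)
    effect[rng.random(M) < 0.02] = "other"
    effect[indel] = np.where(rng.random(indel.sum()) < 0.5, "frameshift", "nonframeshift")
    effect[causal] = "nonsynonymous"

    gene = (mk["chrom"].astype(str).str.replace("chr", "G", regex=False)
            + "_" + (mk["pos"] // 1_000_000).astype(str)).to_numpy(dtype=object)
    gene[causal] = config.causal_gene

    aa = np.array(list("ARNDCQEGHILKMFPSTWYV"))
    codon = rng.integers(1, 999, size=M)
    hgvs_c = np.array([f"c.{r}{p%3000+1}{a}" for r, p, a in zip(mk["ref"], mk["pos"], mk["alt"])], dtype=object)
    hgvs_p = np.array(
        [f"p.{a1}{c}{a2}" for a1, c, a2 in zip(aa[rng.integers(0, 20, M)], codon, aa[rng.integers(0, 20, M)])],
        dtype=object,
    )
    hgvs_p[effect == "synonymous"] = "-"

    novel = rng.random(M) < config.novel_fraction
    novel |= causal
    known_id = np.array([f"rs{7_000_000 + i}" for i in range(M)], dtype=object)
    known_id[novel] = None
    pop_freq = np.round(np.clip(truth.true_freq + rng.normal(0, 0.01, M), 0.0001, 0.9999), 4)
    pop_freq = pop_freq.astype(object)
    pop_freq[novel] = None

    return pd.DataFrame(
        {
            "chrom": mk["chrom"], "pos": mk["pos"], "ref": mk["ref"], "alt": mk["alt"],
            "gene": gene, "effect": effect, "hgvs_c": hgvs_c, "hgvs_p": hgvs_p,
            "known_id": known_id, "pop_freq": pop_freq,
        }
    )


def _write_vcf(path: Path, panel: GenotypePanel, dp: np.ndarray, gq: np.ndarray) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=famphase-simulate"]
    for c, ln in AUTOSOME_LENGTHS.items():
        lines.append(f"##contig=<ID={c},length={ln}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.subjects),
    ]
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    mk = panel.markers
    for i in range(len(panel)):
        cells = [
            f"{gt_str[int(panel.dosages[i, j])]}:{int(dp[i, j])}:{int(gq[i, j])}"
            for j in range(len(panel.subjects))
        ]
        lines.append(
            f"{mk['chrom'][i]}\t{mk['pos'][i]}\t{mk['marker_id'][i]}\t{mk['ref'][i]}\t{mk['alt'][i]}"
            f"\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(cells)
        )
    path.write_text("\n".join(lines) + "\n")


def emit_fixture(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the complete synthetic fixture file set; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_family(config)
    paths = {
        "ped": outdir / "family.ped",
        "vcf": outdir / "variants.vcf",
        "annotation": outdir / "annotation.tsv",
        "bed": outdir / "exons.bed",
        "depth": outdir / "depth.tsv",
        "array": outdir / "array.tsv",
        "truth": outdir / "truth.json",
    }
    paths["ped"].write_text(write_pedigree(sim.pedigree))
    _write_vcf(paths["vcf"], sim.wes_panel, sim.wes_panel.depth, sim.wes_panel.gq)
    ann = sim.annotation.copy()
    ann.to_csv(paths["annotation"], sep="\t", index=False, na_rep="-")
    sim.coverage.exons[["chrom", "start", "end", "name"]].to_csv(
        paths["bed"], sep="\t", index=False, header=False
    )
    write_depth_tsv(sim.coverage, paths["depth"])
    write_genotype_tsv(sim.array_panel, paths["array"])
    paths["truth"].write_text(json.dumps(sim.truth.summary(), indent=1))
    return paths
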