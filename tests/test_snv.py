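import itertools

import numpy as np
import pandas as pd
import pytest

from famphase.linkage import HotSpot
from famphase.panels import MISSING
from famphase.pedigree import Pedigree
from famphase.simulate import default_family
from famphase.snv import (
    VariantSet,
    effect_filter,
    hotspot_intersect,
    known_filter,
    qc_filter,
    render_candidate_table,
    segregation_filter,
)

SAMPLES = ["I-1", "I-2", "II-1", "II-2", "II-3", "II-5", "II-7", "II-9"]
AFFECTED = {"I-1", "II-2", "II-3", "II-5"}


def make_vs(rows, dosage, depth=None, gq=None):
    """rows: (chrom, pos, gene, effect, known_id, pop_freq)."""
    n = len(rows)
    table = pd.DataFrame(
        {
            "marker_id": [f"v{i}" for i in range(n)],
            "chrom": [r[0] for r in rows],
            "pos": [r[1] for r in rows],
            "ref": "A",
            "alt": "G",
            "type": "snv",
            "gene": [r[2] for r in rows],
            "effect": [r[3] for r in rows],
            "hgvs_c": "c.1A>G",
            "hgvs_p": "p.K1R",
            "known_id": [r[4] for r in rows],
            "pop_freq": [r[5] for r in rows],
        }
    )
    dosage = np.asarray(dosage, dtype=np.int8)
    depth = np.full(dosage.shape, 50) if depth is None else np.asarray(depth)
    gq = np.full(dosage.shape, 99) if gq is None else np.asarray(gq)
    return VariantSet(table, SAMPLES, dosage, depth, gq)


def seg_dosage(extra_carrier=None, missing_in=None):
    dos = [[1 if s in AFFECTED else 0 for s in SAMPLES]]
    if extra_carrier:
        dos[0][SAMPLES.index(extra_carrier)] = 1
    if missing_in:
        dos[0][SAMPLES.index(missing_in)] = MISSING
    return dos


ROW = ("chr3", 100, "G1", "nonsynonymous", None, None)


class TestQc:
    def test_one_low_depth_genotype_drops_variant(self):
        depth = np.full((1, 8), 50)
        depth[0, 3] = 9
        assert len(qc_filter(make_vs([ROW], seg_dosage(), depth=depth))) == 0

    def test_clean_variant_kept(self):
        assert len(qc_filter(make_vs([ROW], seg_dosage()))) == 1

    def test_sex_chromosome_dropped_with_flag(self):
        vs = make_vs([("chrX", 5, "G", "nonsynonymous", None, None)], seg_dosage())
        assert len(qc_filter(vs, autosomes_only=True)) == 0
        assert len(qc_filter(vs, autosomes_only=False)) == 1

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        rows = [ROW] * 30
        dosage = rng.integers(0, 3, size=(30, 8))
        depth = rng.integers(5, 60, size=(30, 8))
        gq = rng.integers(10, 100, size=(30, 8))
        vs = make_vs(rows, dosage, depth, gq)
        prev = vs.keys() | set()
        survivors = qc_filter(vs, 10, 30)
        for d, g in [(10, 40), (20, 40), (30, 60)]:
            nxt = qc_filter(vs, d, g)
            assert nxt.keys() <= survivors.keys()
            survivors = nxt


class TestKnown:
    def test_novel_kept_in_both_modes(self):
        vs = make_vs([ROW], seg_dosage())
        assert len(known_filter(vs, "annotate_only")) == 1
        assert len(known_filter(vs, "drop_known")) == 1

    def test_common_variant_dropped_only_in_drop_known(self):
        vs = make_vs([("chr3", 1, "G", "nonsynonymous", "rs1", 0.23)], seg_dosage())
        assert len(known_filter(vs, "annotate_only")) == 1
        assert len(known_filter(vs, "drop_known", max_freq=0.01)) == 0

    def test_id_without_frequency_suffices_to_drop(self):
        vs = make_vs([("chr3", 1, "G", "nonsynonymous", "rs9", None)], seg_dosage())
        assert len(known_filter(vs, "drop_known")) == 0


class TestEffect:
    @pytest.mark.parametrize(
        "effect, kept",
        [
            ("nonsynonymous", True),
            ("synonymous", False),
            ("frameshift", True),
            ("stopgain", True),
            ("other", False),
            (None, False),
        ],
    )
    def test_effect_classes(self, effect, kept):
        vs = make_vs([("chr3", 1, "G", effect, None, None)], seg_dosage())
        assert len(effect_filter(vs)) == (1 if kept else 0)


class TestSegregation:
    def test_perfect_cosegregation_kept(self):
        ped = default_family()
        assert len(segregation_filter(make_vs([ROW], seg_dosage()), ped)) == 1

    def test_unaffected_carrier_fails(self):
        ped = default_family()
        assert len(segregation_filter(make_vs([ROW], seg_dosage(extra_carrier="II-7")), ped)) == 0

    def test_missing_genotype_fails_conservatively(self):
        ped = default_family()
        assert len(segregation_filter(make_vs([ROW], seg_dosage(missing_in="II-2")), ped)) == 0

    def test_homozygous_affected_carrier_allowed(self):
        ped = default_family()
        dos = seg_dosage()
        dos[0][SAMPLES.index("II-3")] = 2
        assert len(segregation_filter(make_vs([ROW], dos), ped)) == 1

    def test_null_survival_probability_bounded(self):
        """Dosages dropped independently of phenotype survive segregation
        no more often than the analytic single-meiosis bound."""
        ped = default_family()
        rng = np.random.default_rng(11)
        n = 20_000
        # het founder gene drop through the core family, phenotype-blind
        f = np.zeros((n, 8), dtype=np.int8)
        f[:, 0] = 1  # I-1 het
        for j in range(2, 8):  # six children inherit from I-1 at random
            f[:, j] = rng.integers(0, 2, size=n)
        vs = make_vs([ROW] * n, f)
        frac = len(segregation_filter(vs, ped)) / n
        bound = 0.5**6  # six phenotype-informative meioses from the het founder
        se = np.sqrt(bound * (1 - bound) / n)
        assert frac <= bound + 3 * se


class TestOrderIndependence:
    def test_qc_effect_segregation_commute(self):
        ped = default_family()
        rng = np.random.default_rng(3)
        n = 200
        rows = [
            ("chr%d" % rng.integers(1, 23), int(rng.integers(1, 10**6)),
             "G", rng.choice(["nonsynonymous", "synonymous", "frameshift", "other"]),
             None, None)
            for _ in range(n)
        ]
        dosage = rng.integers(0, 3, size=(n, 8))
        depth = rng.integers(5, 60, size=(n, 8))
        gq = rng.integers(10, 100, size=(n, 8))
        vs = make_vs(rows, dosage, depth, gq)
        filters = {
            "qc": lambda v: qc_filter(v),
            "eff": effect_filter,
            "seg": lambda v: segregation_filter(v, ped),
        }
        results = set()
        for perm in itertools.permutations(filters.values()):
            out = vs
            for f in perm:
                out = f(out)
            results.add(frozenset(zip(out.table["chrom"], out.table["pos"], out.table["marker_id"])))
        assert len(results) == 1


class TestHotspotIntersect:
    HS = [HotSpot("chr3", 100, 500, ["a", "b"], 1.8)]

    def test_inside_kept_with_max_lod(self):
        vs = hotspot_intersect(make_vs([("chr3", 500, "G", "nonsynonymous", None, None)], seg_dosage()), self.HS)
        assert len(vs) == 1
        assert vs.table["max_lod"].iloc[0] == 1.8

    def test_one_bp_past_end_dropped(self):
        vs = hotspot_intersect(make_vs([("chr3", 501, "G", "nonsynonymous", None, None)], seg_dosage()), self.HS)
        assert len(vs) == 0

    def test_disabled_intersection_passes_all(self):
        vs = hotspot_intersect(
            make_vs([("chr7", 9, "G", "nonsynonymous", None, None)], seg_dosage()), self.HS, enabled=False
        )
        assert len(vs) == 1 and np.isnan(vs.table["max_lod"].iloc[0])

    def test_empty_hotspots_give_empty_table(self, caplog):
        with caplog.at_level("WARNING"):
            vs = hotspot_intersect(make_vs([ROW], seg_dosage()), [])
        assert len(vs) == 0


class TestRender:
    def test_novel_candidate_row(self):
        vs = make_vs([("chr17", 100, "ACTG1", "nonsynonymous", None, None)], seg_dosage())
        vs.table.loc[0, ["hgvs_c", "hgvs_p"]] = ["c.T914C", "p.M305T"]
        out = render_candidate_table(vs)
        assert out.splitlines()[1] == "ACTG1\tchr17\tc.T914C\tp.M305T\t-\t-"

    def test_known_variant_prints_frequency_and_id(self):
        vs = make_vs([("chr11", 5, "OR8G5", "nonsynonymous", "rs2512167", 0.50)], seg_dosage())
        line = render_candidate_table(vs).splitlines()[1]
        assert line.endswith("0.5\trs2512167")

    def test_empty_table_is_header_only(self):
        vs = make_vs([ROW], seg_dosage()).select(np.zeros(1, dtype=bool))
        assert render_candidate_table(vs).splitlines() == [
            "Gene\tChr\tNucleotide variation\tAmino acid variation\tFrequency in 1,000 genome\tdbSNP135"
        ]
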