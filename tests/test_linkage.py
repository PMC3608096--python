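import numpy as np
import pandas as pd
import pytest

from famphase.linkage import (
    DiseaseModel,
    QCParams,
    apply_marker_qc,
    detect_hotspots,
    lod_scan,
    lod_single_point,
    pedigree_log_likelihood,
)
from famphase.panels import MISSING, GenotypePanel, MarkerGenotypes
from famphase.pedigree import Individual, Pedigree

from oracles import brute_force_loglik, random_linkage_instance

MODEL = DiseaseModel()


def nuclear_family(n_children, affections=None):
    inds = [
        Individual("F", sex="male", affection="affected"),
        Individual("M", sex="female", affection="unaffected"),
    ]
    for k in range(n_children):
        aff = affections[k] if affections else ("affected" if k % 2 == 0 else "unaffected")
        inds.append(Individual(f"C{k}", "F", "M", "unknown", aff))
    return Pedigree(inds)


def marker(dosages, freq=0.5):
    return MarkerGenotypes("m", "chr1", 100, "A", "G", dosages, freq)


class TestLikelihood:
    def test_single_het_founder_is_hwe_term(self):
        ped = Pedigree([Individual("A")])
        ll = pedigree_log_likelihood(ped, marker({"A": 1}), MODEL, theta=0.0)
        assert ll == pytest.approx(np.log(2 * 0.5 * 0.5), abs=1e-12)

    def test_loci_factorize_at_theta_half(self):
        """At theta = 1/2 the joint likelihood equals the product of the
        disease-only and marker-only single-locus likelihoods (the scan's
        fast path for the null)."""
        from famphase.linkage import _disease_only_loglik, _marker_only_loglik_batch

        ped = nuclear_family(4)
        dos = {"F": 1, "M": 0, "C0": 1, "C1": 0, "C2": 1, "C3": 0}
        joint = pedigree_log_likelihood(ped, marker(dos, 0.3), MODEL, theta=0.5)
        dosm = np.array([[dos[i.id] for i in ped.individuals]], dtype=np.int8)
        lm = _marker_only_loglik_batch(ped, dosm, np.array([0.3]))[0]
        ld = _disease_only_loglik(ped, MODEL)
        assert joint == pytest.approx(lm + ld, abs=1e-9)

    def test_all_missing_dosages_rejected(self):
        ped = nuclear_family(1)
        with pytest.raises(ValueError, match="likelihood undefined"):
            pedigree_log_likelihood(ped, marker({i: MISSING for i in ped.ids}), MODEL)

    def test_invalid_theta_rejected(self):
        ped = nuclear_family(1)
        with pytest.raises(ValueError, match="theta"):
            pedigree_log_likelihood(ped, marker({"F": 1}), MODEL, theta=0.7)

    @pytest.mark.parametrize("seed", range(6))
    def test_peeling_matches_brute_force(self, seed):
        rng = np.random.default_rng(900 + seed)
        for _ in range(5):
            ped, dos, freq, pen, q, theta = random_linkage_instance(rng)
            bf = brute_force_loglik(ped, dos, freq, pen, q, theta)
            es = pedigree_log_likelihood(
                ped, marker(dos, freq), DiseaseModel(pen, q, 0.0), theta
            )
            if np.isinf(bf) or np.isinf(es):
                assert np.isinf(bf) and np.isinf(es)
            else:
                assert es == pytest.approx(bf, abs=1e-9)


class TestLod:
    @pytest.mark.parametrize("n", range(3, 9))
    def test_phase_unknown_informative_meioses(self, n):
        """Perfect co-segregation through n informative meioses gives
        (n-1)*log10(2) when the carrier parent's phase is unknown."""
        affections = ["affected" if k % 2 == 0 else "unaffected" for k in range(n)]
        ped = nuclear_family(n, affections)
        dos = {"F": 1, "M": 0} | {f"C{k}": (1 if affections[k] == "affected" else 0) for k in range(n)}
        lod = lod_single_point(ped, marker(dos, 0.37), MODEL)
        assert lod == pytest.approx((n - 1) * np.log10(2), abs=1e-6)

    def test_uninformative_marker_gives_zero(self):
        ped = nuclear_family(4)
        dos = {i: 2 for i in ped.ids}
        assert lod_single_point(ped, marker(dos), MODEL) == pytest.approx(0.0, abs=1e-12)

    def test_theta_half_model_gives_zero_everywhere(self):
        ped = nuclear_family(4)
        dos = {"F": 1, "M": 0, "C0": 1, "C1": 0, "C2": 1, "C3": 0}
        m = DiseaseModel(theta=0.5)
        assert lod_single_point(ped, marker(dos, 0.3), m) == pytest.approx(0.0, abs=1e-12)

    def test_ref_alt_relabel_invariance(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            ped, dos, freq, pen, q, theta = random_linkage_instance(rng)
            model = DiseaseModel(pen, q, min(theta, 0.4))
            flipped = {k: (MISSING if v == MISSING else 2 - v) for k, v in dos.items()}
            l1 = lod_single_point(ped, marker(dos, freq), model)
            l2 = lod_single_point(ped, marker(flipped, 1 - freq), model)
            if np.isfinite(l1) or np.isfinite(l2):
                assert l1 == pytest.approx(l2, abs=1e-9)


class TestScanQc:
    def panel(self, depth_val=50, gq_val=99):
        markers = pd.DataFrame(
            [("m1", "chr1", 100, "A", "G"), ("m2", "chrX", 5, "A", "G"), ("m3", "chr2", 7, "A", "G")],
            columns=["marker_id", "chrom", "pos", "ref", "alt"],
        )
        dos = np.array([[1, 0], [1, 0], [1, 1]], dtype=np.int8)
        depth = np.full((3, 2), depth_val)
        gq = np.full((3, 2), gq_val)
        return GenotypePanel(markers, dos, ["a", "b"], depth=depth, gq=gq)

    def test_sex_chromosome_markers_excluded(self):
        kept = apply_marker_qc(self.panel(), QCParams())
        assert set(kept.markers["chrom"]) == {"chr1", "chr2"}

    def test_depth_boundary_inclusive_by_default_exclusive_in_strict(self):
        panel = self.panel(depth_val=10)
        assert len(apply_marker_qc(panel, QCParams(autosomes_only=False))) == 3
        assert len(apply_marker_qc(panel, QCParams(autosomes_only=False, strict=True))) == 0

    def test_low_gq_in_any_subject_drops_marker(self):
        panel = self.panel()
        panel.gq[0, 1] = 29
        kept = apply_marker_qc(panel, QCParams())
        assert "m1" not in set(kept.markers["marker_id"])

    def test_empty_survivor_set_returns_empty_track(self):
        ped = Pedigree([Individual("a", sex="male"), Individual("b", sex="female")])
        track = lod_scan(ped, self.panel(depth_val=1), MODEL)
        assert len(track) == 0


class TestHotspots:
    def track(self, rows):
        return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "lod"])

    def test_three_consecutive_markers_merge(self):
        t = self.track([("a", "chr1", 100, 1.6), ("b", "chr1", 200, 1.6), ("c", "chr1", 300, 1.6)])
        hs = detect_hotspots(t, max_gap=1000)
        assert len(hs) == 1 and hs[0].max_lod == 1.6 and hs[0].n_markers == 3
        assert (hs[0].start, hs[0].end) == (100, 300)

    def test_isolated_peak_below_min_markers_dropped(self):
        t = self.track([("a", "chr1", 100, 3.0)])
        assert detect_hotspots(t, min_markers=2) == []
        assert len(detect_hotspots(t, min_markers=1)) == 1

    def test_clusters_split_by_gap(self):
        t = self.track(
            [("a", "chr1", 100, 2.0), ("b", "chr1", 200, 2.0),
             ("c", "chr1", 5_000_000, 2.0), ("d", "chr1", 5_000_100, 2.0)]
        )
        assert len(detect_hotspots(t, max_gap=1_000_000)) == 2
        assert len(detect_hotspots(t, max_gap=10_000_000)) == 1
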