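"""Pruning, merging, size gating, elastic-network modes, quasi-rigid
decomposition and the intra-domain-contact (Pidc) filter."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from cryptosite import dynamic_filter as dyn
from cryptosite import synthetic_data
from cryptosite.accessibility import Thresholds, residue_rsa
from cryptosite.errors import ConfigError, DataError, StateError
from cryptosite.structio import Atom, Residue, SiteRecord, Structure


def chain_of(plddts, spacing=3.8, start=1):
    residues = []
    for i, plddt in enumerate(plddts):
        residues.append(Residue(start + i, "A",
                                [Atom("CA", "C", (i * spacing, 0.0, 0.0))], plddt))
    return Structure("A", residues)


def segment(positions, xyz):
    return [Residue(p, "A", [Atom("CA", "C", tuple(c))], 90.0)
            for p, c in zip(positions, xyz)]


class TestPrune:
    def test_threshold_split(self):
        s = chain_of([90.0] * 50 + [40.0] * 10 + [90.0] * 50)
        segments = dyn.prune_low_confidence(s, 65.0)
        assert [len(seg) for seg in segments] == [50, 50]
        assert segments[1][0].position == 61  # numbering preserved

    def test_all_high_single_segment(self):
        s = chain_of([90.0] * 30)
        segments = dyn.prune_low_confidence(s, 65.0)
        assert len(segments) == 1 and len(segments[0]) == 30

    def test_planted_loop_boundaries(self, globule):
        structure, truth = globule
        segments = dyn.prune_low_confidence(structure, 65.0)
        removed = {r.position for r in structure.residues} \
            - {r.position for seg in segments for r in seg}
        assert removed == set(truth.low_confidence_positions)


class TestMerge:
    def close_pair_segments(self, n_pairs):
        # two parallel strands; n_pairs residues of B within 5 A of A
        a = segment(range(1, 11), [(i * 3.8, 0, 0) for i in range(10)])
        b_coords = [(i * 3.8, 4.5, 0) if i < n_pairs else (i * 3.8, 30.0, 0)
                    for i in range(10)]
        b = segment(range(21, 31), b_coords)
        return [a, b]

    def test_contacting_segments_merge(self):
        entries = dyn.merge_entries(self.close_pair_segments(8), "P")
        assert len(entries) == 1 and len(entries[0]) == 20

    def test_four_pairs_stay_separate(self):
        entries = dyn.merge_entries(self.close_pair_segments(4), "P")
        assert len(entries) == 2

    def test_transitive_merging(self):
        a = segment(range(1, 11), [(i * 3.8, 0, 0) for i in range(10)])
        b = segment(range(21, 31), [(i * 3.8, 4.5, 0) for i in range(10)])
        c = segment(range(41, 51), [(i * 3.8, 9.0, 0) for i in range(10)])
        entries = dyn.merge_entries([a, b, c], "P")
        # A-B close, B-C close, A-C far: one entry by connected components
        assert len(entries) == 1 and len(entries[0]) == 30

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            dyn.merge_entries([], "P")


class TestSizeGate:
    @pytest.mark.parametrize("n,kept", [(39, 0), (40, 1)])
    def test_boundary(self, n, kept):
        entry = dyn.Entry("P", segment(range(1, n + 1),
                                       [(i * 3.8, 0, 0) for i in range(n)]))
        out, _ = dyn.size_gate([entry])
        assert len(out) == kept

    def test_site_in_dropped_entry_excluded(self):
        entry = dyn.Entry("P", segment(range(1, 11),
                                       [(i * 3.8, 0, 0) for i in range(10)]))
        site = SiteRecord("P", 5, "A", "phospho", status="cryptic")
        _, affected = dyn.size_gate([entry], [site])
        assert site.status == "excluded:small_domain" and affected == [site]


class TestRefilterRsa:
    def test_loop_occluded_site_exposed_after_pruning(self, globule):
        structure, truth = globule
        segments = dyn.prune_low_confidence(structure, 65.0)
        entries = dyn.merge_entries(segments, truth.accession)
        assert len(entries) == 1
        occluded = truth.positions_with("low_confidence_occluded")[0]
        core = truth.positions_with("core_cryptic")[0]
        sites = [SiteRecord(truth.accession, occluded, "S", "phospho",
                            status="cryptic"),
                 SiteRecord(truth.accession, core, "S", "phospho",
                            status="cryptic")]
        dyn.refilter_rsa(entries[0], sites)
        assert sites[0].status == "excluded:exposed_after_pruning"
        assert sites[1].status == "cryptic"  # core occluders were confident

    def test_full_chain_entry_is_noop(self, hinge):
        structure, truth = hinge
        entry = dyn.Entry(truth.accession, structure.residues)
        pos = truth.positions_with("core_cryptic")[0]
        before = residue_rsa(structure)[pos][1]
        site = SiteRecord(truth.accession, pos, "S", "phospho", status="cryptic")
        dyn.refilter_rsa(entry, [site])
        assert site.rsa == pytest.approx(before, abs=1e-9)

    def test_site_outside_entry_is_state_error(self):
        entry = dyn.Entry("P", segment(range(1, 11),
                                       [(i * 3.8, 0, 0) for i in range(10)]))
        site = SiteRecord("P", 99, "A", "phospho", status="cryptic")
        with pytest.raises(StateError):
            dyn.refilter_rsa(entry, [site])


class TestEnmModes:
    def test_rigid_body_null_space(self, hinge):
        structure, truth = hinge
        entry = dyn.Entry(truth.accession, structure.residues)
        modes = dyn.enm_modes(entry)
        ev = modes.all_eigenvalues
        assert np.all(ev >= -1e-9 * abs(ev[-1]))
        assert np.all(ev[:6] < 1e-8 * ev[6])  # exactly six rigid-body modes

    @staticmethod
    def _rigid_fit_residual(v, x):
        """Residual norm^2 after fitting v_i = t + omega x (x_i - xbar)."""
        dx = x - x.mean(axis=0)
        n = len(x)
        design = np.zeros((3 * n, 6))
        for i in range(n):
            design[3 * i:3 * i + 3, :3] = np.eye(3)
            d = dx[i]
            design[3 * i:3 * i + 3, 3:] = np.array(
                [[0, d[2], -d[1]], [-d[2], 0, d[0]], [d[1], -d[0], 0]])
        coef, *_ = np.linalg.lstsq(design, v.ravel(), rcond=None)
        residual = v.ravel() - design @ coef
        return float((residual ** 2).sum())

    def test_hinge_mode_dominated_by_interbody_motion(self, hinge):
        """The softest mode with real body participation moves the bodies as
        rigid units against each other (>70% of its body norm is rigid)."""
        structure, truth = hinge
        entry = dyn.Entry(truth.accession, structure.residues)
        modes = dyn.enm_modes(entry)
        body = np.array([truth.domain_labels[p] for p in entry.index_map])
        x = modes.ca_coords
        for m in range(modes.eigenvectors.shape[2]):
            v = modes.eigenvectors[:, :, m]
            body_norm = (v[body >= 0] ** 2).sum()
            if body_norm < 0.5 * (v ** 2).sum():
                continue  # linker-dominated mode
            nonrigid = (self._rigid_fit_residual(v[body == 0], x[body == 0])
                        + self._rigid_fit_residual(v[body == 1], x[body == 1]))
            assert nonrigid / body_norm < 0.3
            # and the two bodies actually move differently
            assert self._rigid_fit_residual(v[body >= 0], x[body >= 0]) \
                > 10 * nonrigid
            break
        else:
            pytest.fail("no mode with majority body participation found")

    def test_disconnected_network_names_components(self):
        far = segment(range(1, 5), [(0, 0, 0), (3.8, 0, 0),
                                    (100, 0, 0), (103.8, 0, 0)])
        entry = dyn.Entry("P", far)
        with pytest.raises(DataError, match="2 components"):
            dyn.enm_modes(entry)


class TestQuasiRigidDecompose:
    def test_hinge_bodies_recovered(self, hinge):
        structure, truth = hinge
        entry = dyn.Entry(truth.accession, structure.residues)
        decomposition = dyn.quasi_rigid_decompose(entry, dyn.enm_modes(entry))
        body_positions = [p for p, l in truth.domain_labels.items() if l >= 0]
        ari = adjusted_rand_score(
            [truth.domain_labels[p] for p in body_positions],
            [decomposition.labels[p] for p in body_positions])
        assert ari == pytest.approx(1.0)  # linker residues may go either way

    def test_single_rigid_body_low_quality_labels_emitted(self):
        blob = synthetic_data._lattice_blob(60)
        rng = np.random.default_rng(0)
        residues = []
        for i, p in enumerate(blob):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            residues.append(Residue(i + 1, "A",
                                    [Atom("CA", "C", tuple(p)),
                                     Atom("CB", "C", tuple(p + 1.5 * direction))],
                                    90.0))
        entry = dyn.Entry("P", residues)
        decomposition = dyn.quasi_rigid_decompose(entry, dyn.enm_modes(entry))
        hinge_structure, hinge_truth = synthetic_data.make_hinge_fixture(seed=1)
        hinge_entry = dyn.Entry("H", hinge_structure.residues)
        hinge_dec = dyn.quasi_rigid_decompose(hinge_entry,
                                              dyn.enm_modes(hinge_entry))
        assert set(decomposition.labels) == set(entry.index_map)
        assert decomposition.quality[2] < hinge_dec.quality[hinge_dec.chosen_k]

    def test_quality_invariant_under_label_permutation(self, hinge):
        structure, truth = hinge
        entry = dyn.Entry(truth.accession, structure.residues)
        modes = dyn.enm_modes(entry)
        d1 = dyn.quasi_rigid_decompose(entry, modes, seed=0)
        d2 = dyn.quasi_rigid_decompose(entry, modes, seed=0)
        assert d1.quality == d2.quality and d1.labels == d2.labels  # deterministic

    def test_sigma_objectivity_under_rigid_transform(self, hinge):
        structure, truth = hinge
        entry = dyn.Entry(truth.accession, structure.residues)
        sigma = dyn.distance_fluctuations(dyn.enm_modes(entry))
        rot = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        shift = np.array([5.0, -3.0, 8.0])
        moved = [Residue(r.position, r.aa,
                         [Atom(a.name, a.element, tuple(rot @ np.array(a.xyz) + shift))
                          for a in r.atoms], r.plddt)
                 for r in structure.residues]
        sigma2 = dyn.distance_fluctuations(dyn.enm_modes(dyn.Entry("P", moved)))
        assert np.abs(sigma - sigma2).max() <= 1e-8 * sigma.max()

    def test_oversized_k_rejected(self, hinge):
        structure, truth = hinge
        entry = dyn.Entry(truth.accession, structure.residues)
        with pytest.raises(ConfigError):
            dyn.quasi_rigid_decompose(entry, dyn.enm_modes(entry),
                                      k_max=len(entry))


class TestPidc:
    def hinge_setup(self, hinge):
        structure, truth = hinge
        entry = dyn.Entry(truth.accession, structure.residues)
        decomposition = dyn.quasi_rigid_decompose(entry, dyn.enm_modes(entry))
        return structure, truth, entry, decomposition

    def test_deep_site_all_intra_domain(self, hinge):
        structure, truth, entry, decomposition = self.hinge_setup(hinge)
        pos = truth.positions_with("core_cryptic")[0]
        res = dyn.compute_pidc(SiteRecord(truth.accession, pos, "S", "phospho"),
                               entry, decomposition)
        assert res.pidc >= 0.8
        assert res.pidc == res.n_same_domain / res.n_neighbors

    def test_boundary_site_below_threshold(self, hinge):
        structure, truth, entry, decomposition = self.hinge_setup(hinge)
        pos = truth.positions_with("boundary")[0]
        res = dyn.compute_pidc(SiteRecord(truth.accession, pos, "S", "phospho"),
                               entry, decomposition)
        assert res.pidc < 0.8

    def test_isolated_site_is_data_error(self):
        residues = segment([1, 2], [(0, 0, 0), (50, 0, 0)])
        entry = dyn.Entry("P", residues)
        decomposition = dyn.RigidDecomposition(labels={1: 0, 2: 0},
                                               quality={2: 0.0}, chosen_k=2)
        with pytest.raises(DataError):
            dyn.compute_pidc(SiteRecord("P", 1, "A", "phospho"), entry,
                             decomposition)


class TestApplyDynamicFilter:
    def fake_entry(self):
        # 12 residues in two spatial clumps labelled as two domains
        coords = [(i * 3.0, 0, 0) for i in range(6)] \
            + [(i * 3.0, 4.0, 0) for i in range(6)]
        residues = segment(range(1, 13), coords)
        entry = dyn.Entry("P", residues)
        labels = {p: (0 if p <= 6 else 1) for p in range(1, 13)}
        return entry, dyn.RigidDecomposition(labels=labels, quality={2: 0.9},
                                             chosen_k=2)

    def test_exact_threshold_retained(self, monkeypatch):
        entry, decomposition = self.fake_entry()
        site = SiteRecord("P", 3, "A", "phospho", status="cryptic")
        monkeypatch.setattr(dyn, "compute_pidc",
                            lambda *a, **k: dyn.PidcResult(3, 10, 8))
        dyn.apply_dynamic_filter([site], entry, decomposition)
        assert site.status == "cryptic"  # 0.80 is retained, not excluded

    def test_below_threshold_excluded(self, monkeypatch):
        entry, decomposition = self.fake_entry()
        site = SiteRecord("P", 3, "A", "phospho", status="cryptic")
        monkeypatch.setattr(dyn, "compute_pidc",
                            lambda *a, **k: dyn.PidcResult(3, 100, 79))
        dyn.apply_dynamic_filter([site], entry, decomposition)
        assert site.status == "excluded:boundary"

    def test_true_vs_false_cryptic_exemplars(self, hinge):
        """Deep-core site retained, interface site excluded (the planted
        analogue of a true and a false cryptic phosphosite)."""
        structure, truth = hinge
        entry = dyn.Entry(truth.accession, structure.residues)
        decomposition = dyn.quasi_rigid_decompose(entry, dyn.enm_modes(entry))
        deep = truth.positions_with("core_cryptic")[0]
        boundary = truth.positions_with("boundary")[0]
        sites = [SiteRecord(truth.accession, deep, "S", "phospho", status="cryptic"),
                 SiteRecord(truth.accession, boundary, "S", "phospho",
                            status="cryptic")]
        dyn.apply_dynamic_filter(sites, entry, decomposition)
        assert sites[0].status == "cryptic"
        assert sites[1].status == "excluded:boundary"
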