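import numpy as np
import pytest

from whisker_connectome import (
    ReferenceConnectionSet,
    ThresholdSet,
    binarize_consensus,
    build_line_matrices,
    calibrate,
    extract_subnetwork,
    merge_hemispheres,
)
from whisker_connectome.calibration import apply_per_line
from whisker_connectome.errors import CalibrationError
from whisker_connectome.matrices import MergedMatrixSet
from whisker_connectome.records import VARIABLES
from whisker_connectome.specificity import gate_experiments


def _merged(nodes, density, scale=None, measured=None):
    """Square MergedMatrixSet with the other variables as scaled copies."""
    density = np.asarray(density, dtype=float)
    scale = scale or {"density": 1.0, "intensity": 100.0, "energy": 10.0, "volume": 0.5}
    variables = {v: density * scale[v] for v in VARIABLES}
    variables["density"] = np.clip(variables["density"], 0, 1)
    n = len(nodes)
    return MergedMatrixSet(
        line_id="wild",
        sources=list(nodes),
        variables=variables,
        measured=np.ones(n, dtype=bool) if measured is None else np.asarray(measured),
    )


class TestCalibrate:
    def test_threshold_is_min_over_reference_edges(self):
        nodes = ["A", "B", "C"]
        density = np.array([[0.0, 0.3, 0.05], [0.2, 0.0, 0.05], [0.05, 0.05, 0.0]])
        ref = ReferenceConnectionSet([("A", "B"), ("B", "A")])
        theta = calibrate(_merged(nodes, density), ref)
        assert theta.density == pytest.approx(0.2)
        assert theta.intensity == pytest.approx(20.0)

    def test_single_reference_edge(self):
        nodes = ["A", "B"]
        density = np.array([[0.0, 0.37], [0.0, 0.0]])
        theta = calibrate(_merged(nodes, density), ReferenceConnectionSet([("A", "B")]))
        assert theta.density == pytest.approx(0.37)
        assert theta.volume == pytest.approx(0.37 * 0.5)

    def test_planted_floor_recovered(self, bundle7):
        records = gate_experiments(bundle7.experiments, "inclusion")
        wide = build_line_matrices(records, "wild", bundle7.ontology)
        merged = extract_subnetwork(
            merge_hemispheres(wide), bundle7.panel.extended57, bundle7.ontology
        )
        theta = calibrate(merged, bundle7.reference)
        assert theta.as_dict() == pytest.approx(bundle7.config.signal_floors)

    def test_sweep_matches_closed_form(self):
        nodes = ["A", "B", "C"]
        density = np.array([[0.0, 0.3, 0.05], [0.2, 0.0, 0.05], [0.05, 0.05, 0.0]])
        m = _merged(nodes, density)
        ref = ReferenceConnectionSet([("A", "B"), ("B", "A")])
        exact = calibrate(m, ref, method="closed_form")
        swept = calibrate(m, ref, method="sweep", sweep_steps=100_000)
        for v in VARIABLES:
            assert swept[v] == pytest.approx(exact[v], rel=1e-3)
            assert swept[v] <= exact[v] + 1e-12  # grid approaches from below

    def test_zero_reference_value_is_infeasible(self):
        nodes = ["A", "B"]
        density = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(CalibrationError, match=r"\(A, B\) has zero density"):
            calibrate(_merged(nodes, density), ReferenceConnectionSet([("A", "B")]))

    def test_unmeasured_reference_row_is_infeasible(self):
        nodes = ["A", "B"]
        density = np.array([[0.0, 0.5], [0.0, 0.0]])
        m = _merged(nodes, density, measured=[False, True])
        with pytest.raises(CalibrationError, match="unmeasured"):
            calibrate(m, ReferenceConnectionSet([("A", "B")]))

    def test_tightness_next_value_drops_a_reference_edge(self):
        nodes = ["A", "B", "C"]
        density = np.array([[0.0, 0.3, 0.05], [0.2, 0.0, 0.05], [0.05, 0.05, 0.0]])
        m = _merged(nodes, density)
        ref = ReferenceConnectionSet([("A", "B"), ("B", "A")])
        theta = calibrate(m, ref)
        detected = set(binarize_consensus(m, theta).edges())
        assert set(ref.pairs) <= detected
        for v in VARIABLES:
            observed = np.unique(m.variables[v][m.variables[v] > theta[v]])
            bumped = theta.replace_variable(v, float(observed.min()))
            lost = set(ref.pairs) - set(binarize_consensus(m, bumped).edges())
            assert lost, f"bumping {v} should lose a reference edge"


class TestBinarize:
    def test_consensus_requires_all_four(self):
        nodes = ["A", "B"]
        density = np.array([[0.0, 0.5], [0.0, 0.0]])
        m = _merged(nodes, density)
        m.variables["energy"][0, 1] = 0.1  # fails one of four thresholds
        theta = ThresholdSet(density=0.5, intensity=50.0, energy=5.0, volume=0.25)
        assert binarize_consensus(m, theta).edges() == []

    def test_edge_exactly_at_thresholds_detected(self):
        nodes = ["A", "B"]
        density = np.array([[0.0, 0.5], [0.0, 0.0]])
        m = _merged(nodes, density)
        theta = ThresholdSet(density=0.5, intensity=50.0, energy=5.0, volume=0.25)
        assert binarize_consensus(m, theta).edges() == [("A", "B")]

    def test_all_zero_matrices_give_empty_connectome(self):
        m = _merged(["A", "B"], np.zeros((2, 2)))
        theta = ThresholdSet(density=0.1, intensity=1.0, energy=1.0, volume=0.1)
        bc = binarize_consensus(m, theta)
        assert bc.edge_count() == 0

    def test_unmeasured_rows_all_zero_and_flagged(self):
        density = np.array([[0.0, 0.9], [0.9, 0.0]])
        m = _merged(["A", "B"], density, measured=[False, True])
        theta = ThresholdSet(density=0.1, intensity=1.0, energy=1.0, volume=0.01)
        bc = binarize_consensus(m, theta)
        assert bc.adjacency[0].sum() == 0  # no data ≠ no connection
        assert not bc.measured[0]
        assert bc.edges() == [("B", "A")]

    def test_monotone_in_thresholds(self, rng):
        nodes = list("ABCDE")
        density = rng.random((5, 5))
        np.fill_diagonal(density, 0)
        m = _merged(nodes, density)
        lo = ThresholdSet(density=0.2, intensity=20.0, energy=2.0, volume=0.1)
        hi = ThresholdSet(density=0.4, intensity=40.0, energy=4.0, volume=0.2)
        assert set(binarize_consensus(m, hi).edges()) <= set(
            binarize_consensus(m, lo).edges()
        )


class TestApplyPerLine:
    def test_identical_lines_give_identical_connectomes(self, bundle7):
        records = gate_experiments(bundle7.experiments, "inclusion")
        wide = build_line_matrices(records, "wild", bundle7.ontology)
        theta = ThresholdSet(**bundle7.config.signal_floors)
        out = apply_per_line([wide, wide], theta)
        assert len(out) == 1  # same line id → one entry, deterministic

    def test_calibrated_map_contains_reference(self, bundle7):
        records = gate_experiments(bundle7.experiments, "inclusion")
        wide = build_line_matrices(records, "wild", bundle7.ontology)
        merged = extract_subnetwork(
            merge_hemispheres(wide), bundle7.panel.extended57, bundle7.ontology
        )
        theta = calibrate(merged, bundle7.reference)
        detected = set(binarize_consensus(merged, theta).edges())
        assert set(bundle7.reference.pairs) <= detected
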