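"""Quadratic movement law, superimposition, validation and method error."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orthofem import movement as mv
from orthofem.movement import (
    CANONICAL_LAW,
    CalibrationPoint,
    MovementRecord,
    QuadraticLaw,
    dahlberg_error,
    fit,
    landmark_displacement,
    load_calibration_table,
    load_validation_table,
    predict,
    records_from_table,
    rigid_superimpose,
    round_half_away,
    validate,
)


class TestPredict:
    @pytest.mark.parametrize(
        "stress, expected_mm",
        [(0.063, 1.378), (0.030, 0.694), (0.048, 0.268), (0.0, 5.667)],
    )
    def test_known_predictions(self, stress, expected_mm):
        assert round_half_away(predict(CANONICAL_LAW, stress), 3) == expected_mm

    def test_rejects_non_finite_stress(self):
        with pytest.raises(ValueError):
            predict(CANONICAL_LAW, float("nan"))

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.0005, 3) == 0.001
        assert round_half_away(-0.0005, 3) == -0.001
        assert round_half_away(2.675, 2) == 2.68  # bankers' rounding would give 2.67


def _normal_equations_fit(x, y):
    """Independent dense quadratic LS oracle via the normal equations."""
    A = np.column_stack([x**2, x, np.ones_like(x)])
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestFit:
    def test_exact_interpolation(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        pts = [CalibrationPoint("C1D", "T0", xi, 2 * xi**2 + 3 * xi + 1) for xi in x]
        report = fit(pts)
        assert np.allclose([report.law.a, report.law.b, report.law.c], [2, 3, 1], atol=1e-9)
        assert report.rmse < 1e-9

    def test_matches_normal_equations_on_calibration_table(self):
        pts = load_calibration_table()
        report = fit(pts)
        x = np.array([p.stress for p in pts])
        y = np.array([p.movement for p in pts])
        oracle = _normal_equations_fit(x, y)
        ours = np.array([report.law.a, report.law.b, report.law.c])
        assert np.all(np.abs(ours - oracle) <= 1e-6 * np.abs(oracle))

    def test_rank_deficiency_raises(self):
        pts = [CalibrationPoint("C1D", "T0", 0.05, 1.0), CalibrationPoint("C1D", "T1", 0.06, 1.1)]
        with pytest.raises(ValueError, match="distinct"):
            fit(pts)

    def test_exclude_landmark_filter(self):
        pts = load_calibration_table()
        report = fit(pts, exclude_landmarks=["C1M"])
        assert report.n_points == 8

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.floats(-500, 3000),
        b=st.floats(-300, 300),
        c=st.floats(-5, 10),
    )
    def test_roundtrip_recovers_any_law(self, a, b, c):
        """Fitting noiseless predictions of a law recovers that law."""
        law = QuadraticLaw(a, b, c)
        x = np.linspace(0.02, 0.08, 7)
        pts = [
            CalibrationPoint("C1D", f"T{i}", xi, max(0.0, float(law(xi))))
            for i, xi in enumerate(x)
            if law(xi) >= 0
        ]
        if len(pts) < 4:
            return
        got = fit(pts).law
        scale = max(1.0, abs(a), abs(b), abs(c))
        assert np.allclose([got.a, got.b, got.c], [p for p in (a, b, c)], atol=1e-6 * scale)

    def test_parameter_recovery_under_noise(self):
        """Noisy synthetic calibration recovers coefficients within 3 SE."""
        rng = np.random.default_rng(7)
        n, sigma = 50, 0.05
        x = rng.uniform(0.02, 0.08, n)
        y = np.asarray(CANONICAL_LAW(x)) + rng.normal(0, sigma, n)
        y = np.clip(y, 0.0, None)
        pts = [CalibrationPoint("C1D", f"T{i}", xi, yi) for i, (xi, yi) in enumerate(zip(x, y))]
        report = fit(pts)
        A = np.column_stack([x**2, x, np.ones_like(x)])
        cov = sigma**2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        est = np.array([report.law.a, report.law.b, report.law.c])
        truth = np.array([CANONICAL_LAW.a, CANONICAL_LAW.b, CANONICAL_LAW.c])
        assert np.all(np.abs(est - truth) <= 3 * se)


def _random_rigid(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.normal(scale=2.0, size=3)


class TestRigidSuperimpose:
    def test_identity_on_identical_clouds(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        tr = rigid_superimpose(pts, pts)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0, atol=1e-12)

    def test_exact_recovery_of_constructed_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg about z
        t = np.array([1.0, 2.0, 3.0])
        moved = pts @ Rz.T + t
        tr = rigid_superimpose(fixed=moved, moving=pts)
        assert np.abs(tr.rotation - Rz).max() < 1e-10
        assert np.abs(tr.translation - t).max() < 1e-10

    def test_optimality_against_random_transforms(self):
        """Kabsch RMSD beats 1000 random rigid transforms on noisy data."""
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 3))
        R, t = _random_rigid(rng)
        noisy = pts @ R.T + t + rng.normal(scale=0.01, size=pts.shape)
        tr = rigid_superimpose(fixed=noisy, moving=pts)
        best = np.sqrt(np.mean(np.sum((tr.apply(pts) - noisy) ** 2, axis=1)))
        for _ in range(1000):
            Rr, tr_r = _random_rigid(rng)
            rmsd = np.sqrt(np.mean(np.sum((pts @ Rr.T + tr_r - noisy) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 3))
        R, t = _random_rigid(rng)
        moved = pts @ R.T + t
        perm = rng.permutation(9)
        tr1 = rigid_superimpose(moved, pts)
        tr2 = rigid_superimpose(moved[perm], pts[perm])
        assert np.abs(tr1.rotation - tr2.rotation).max() < 1e-10
        assert np.abs(tr1.translation - tr2.translation).max() < 1e-10

    def test_collinear_points_raise(self):
        pts = np.outer(np.arange(5.0), np.array([1.0, 1.0, 0.0]))
        with pytest.raises(ValueError, match="degenerate"):
            rigid_superimpose(pts + 1.0, pts)


class TestLandmarkDisplacement:
    def test_zero_for_identical_positions(self):
        lm = {"C1D": np.array([1.0, 0, 0]), "C2D": np.array([0, 1.0, 0]), "C1M": np.zeros(3)}
        tr = mv.RigidTransform.identity()
        assert all(v == 0 for v in landmark_displacement(tr, lm, lm).values())

    @pytest.mark.parametrize(
        "shift, expected", [((0.5, 0, 0), 0.5), ((0.3, 0.4, 0.0), 0.5)]
    )
    def test_pure_translation(self, shift, expected):
        lm = {"C1D": np.array([1.0, 0, 0]), "C2D": np.array([0, 1.0, 0]), "C1M": np.zeros(3)}
        after = {k: v + np.asarray(shift) for k, v in lm.items()}
        disp = landmark_displacement(mv.RigidTransform.identity(), lm, after)
        assert all(abs(v - expected) < 1e-12 for v in disp.values())

    def test_id_mismatch_raises(self):
        with pytest.raises(KeyError):
            landmark_displacement(
                mv.RigidTransform.identity(),
                {"C1D": np.zeros(3)},
                {"C2D": np.zeros(3)},
            )


class TestValidate:
    def test_printed_table_ranges(self):
        records = records_from_table(load_validation_table(), CANONICAL_LAW)
        summary = validate(records)
        assert (summary.min_diff, summary.max_diff) == (0.003, 0.085)
        assert (summary.min_percent, summary.max_percent) == (0.36, 8.96)

    def test_every_printed_cell_reproduced(self):
        table = load_validation_table()
        records = records_from_table(table, CANONICAL_LAW)
        for rec, row in zip(records, table.itertuples()):
            assert rec.predicted_display == float(row.predicted_mm)
            assert rec.diff_display == float(row.diff_mm)
            assert abs(rec.percent_display - float(row.percent)) <= 0.06

    def test_perfect_agreement_gives_zero(self):
        records = [
            MovementRecord("C1D", "T0", 0.05, predicted=1.0, clinical=1.0),
            MovementRecord("C2D", "T0", 0.04, predicted=0.5, clinical=0.5),
        ]
        summary = validate(records)
        assert summary.max_diff == 0.0 and summary.max_percent == 0.0

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            validate([])


class TestDahlberg:
    def test_identical_lists_give_zero(self):
        assert dahlberg_error([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_analytic_value(self):
        # differences (1, 1), n = 2 -> sqrt(2 / 4)
        assert dahlberg_error([1.0, 2.0], [0.0, 1.0]) == pytest.approx(0.70711, abs=1e-5)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=40), rng.normal(size=40)
        oracle = (sum((ai - bi) ** 2 for ai, bi in zip(a, b)) / (2 * len(a))) ** 0.5
        assert dahlberg_error(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            dahlberg_error([1.0], [1.0, 2.0])
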