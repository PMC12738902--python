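"""Constant-velocity Kalman filter over box state (cx, cy, aspect, height).

The 8-dimensional state stacks the measurement (center-x, center-y, aspect
ratio w/h, height) with its per-frame velocities. Process and measurement
noise scale with the current box height — the convention of appearance-based
tracking-by-detection — so near targets carry proportionally larger
uncertainty than far ones. The four coordinates evolve as decoupled
position/velocity pairs, which is what the closed-form scalar oracle in the
test suite exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

# squared Mahalanobis gate: chi-square 0.95 quantile at 4 degrees of freedom
CHI2_GATE_4DOF = 9.4877


@dataclass
class KalmanState:
    mean: np.ndarray  # shape (8,)
    covariance: np.ndarray  # shape (8, 8), symmetric PSD

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (8,) or self.covariance.shape != (8, 8):
            raise ValueError("KalmanState needs an 8-vector mean and 8x8 covariance")


@dataclass
class KalmanFilter:
    """Filter parameters; the per-track state lives in :class:`KalmanState`.

    ``std_weight_position`` and ``std_weight_velocity`` multiply the box
    height to give the noise standard deviations (defaults 1/20 and 1/160).
    Setting both to zero yields a noise-free filter that locks onto a
    constant-velocity trajectory after two updates.
    """

    std_weight_position: float = 1.0 / 20
    std_weight_velocity: float = 1.0 / 160
    _motion_mat: np.ndarray = field(init=False, repr=False)
    _update_mat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._motion_mat = np.eye(8)
        self._motion_mat[:4, 4:] = np.eye(4)  # dt = 1 frame
        self._update_mat = np.eye(4, 8)

    def initiate(self, measurement: np.ndarray) -> KalmanState:
        """Start a track from an unassociated box (cx, cy, a, h); velocities 0."""
        m = np.asarray(measurement, dtype=float)
        if m.shape != (4,):
            raise ValueError(f"measurement must be (cx, cy, a, h), got shape {m.shape}")
        h = m[3]
        if h <= 0:
            raise ValueError(f"non-positive box height {h}")
        mean = np.concatenate([m, np.zeros(4)])
        wp, wv = self.std_weight_position, self.std_weight_velocity
        # zero noise weights describe a noise-free filter: keep unit initial
        # uncertainty so updates can still correct position and velocity
        sp = 2 * wp * h if wp > 0 else 1.0
        sv = 10 * wv * h if wv > 0 else 1.0
        std = np.array([sp, sp, 1e-2, sp, sv, sv, 1e-5, sv])
        return KalmanState(mean, np.diag(np.square(std)))

    def _motion_cov(self, h: float) -> np.ndarray:
        wp, wv = self.std_weight_position, self.std_weight_velocity
        std = np.array([wp * h, wp * h, 1e-2, wp * h, wv * h, wv * h, 1e-5, wv * h])
        return np.diag(np.square(std))

    def _innovation_cov(self, h: float) -> np.ndarray:
        wp = self.std_weight_position
        s = wp * h if wp > 0 else 1e-9  # ridge keeps the update well-posed
        std = np.array([s, s, 1e-1, s])
        return np.diag(np.square(std))

    def predict(self, state: KalmanState) -> KalmanState:
        """Propagate one frame under the constant-velocity model."""
        F = self._motion_mat
        mean = F @ state.mean
        cov = F @ state.covariance @ F.T + self._motion_cov(state.mean[3])
        return KalmanState(mean, (cov + cov.T) / 2.0)

    def project(self, state: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        """State distribution in measurement space (adds measurement noise)."""
        H = self._update_mat
        mean = H @ state.mean
        cov = H @ state.covariance @ H.T + self._innovation_cov(state.mean[3])
        return mean, cov

    def update(self, state: KalmanState, measurement: np.ndarray) -> KalmanState:
        """Condition the state on an associated measurement (cx, cy, a, h)."""
        m = np.asarray(measurement, dtype=float)
        proj_mean, proj_cov = self.project(state)
        try:
            chol = scipy.linalg.cho_factor(proj_cov, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError as exc:
            raise ValueError("singular innovation covariance") from exc
        gain = scipy.linalg.cho_solve(
            chol, (state.covariance @ self._update_mat.T).T, check_finite=False
        ).T
        mean = state.mean + gain @ (m - proj_mean)
        cov = state.covariance - gain @ proj_cov @ gain.T
        if mean[3] <= 0:
            raise ValueError(f"update produced non-positive height {mean[3]}")
        return KalmanState(mean, (cov + cov.T) / 2.0)

    def gating_distance(
        self, state: KalmanState, measurements: np.ndarray
    ) -> np.ndarray:
        """Squared Mahalanobis distance of measurements from the projected state.

        ``measurements`` has shape (n, 4); returns shape (n,). Zero exactly
        when a measurement equals the projected mean.
        """
        proj_mean, proj_cov = self.project(state)
        m = np.atleast_2d(np.asarray(measurements, dtype=float))
        chol = np.linalg.cholesky(proj_cov)
        z = scipy.linalg.solve_triangular(
            chol, (m - proj_mean).T, lower=True, check_finite=False
        )
        return np.sum(z * z, axis=0)
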