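"""Per-feature, per-timepoint standardization.

Each feature (species abundance or metabolite concentration) is centered and
scaled to unit variance separately at every time point, using training-data
statistics only by default — hold-out statistics never leak into the scaler
unless the ``normalize_all`` toggle is set when fitting.  The population
(1/N) variance convention is used, matching the defining formulas.
"""

from __future__ import annotations

import numpy as np


class FeatureScaler:
    """Standardizes a (samples, timepoints, features) array per (k, feature).

    Degenerate features (zero variance) get their standard deviation floored
    at *eps* so the transform maps them to 0 and the round trip stays exact.
    """

    def __init__(self, eps: float = 1e-8):
        self.eps = eps
        self.mu: np.ndarray | None = None     # (T, D)
        self.sigma: np.ndarray | None = None  # (T, D)

    def fit(self, data: np.ndarray) -> "FeatureScaler":
        data = np.asarray(data, dtype=float)
        if data.ndim != 3 or data.shape[0] == 0:
            raise ValueError("expected a non-empty (samples, timepoints, features) array")
        self.mu = data.mean(axis=0)
        self.sigma = np.maximum(data.std(axis=0), self.eps)  # population (1/N) std
        return self

    def _check(self) -> None:
        if self.mu is None:
            raise RuntimeError("scaler has not been fitted")

    def transform(self, data: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(data, dtype=float) - self.mu) / self.sigma

    def inverse_transform(self, data: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(data, dtype=float) * self.sigma + self.mu

    def transform_at(self, k: int, x: np.ndarray) -> np.ndarray:
        """Standardize a state vector (or batch) using timepoint *k* statistics."""
        self._check()
        return (np.asarray(x, dtype=float) - self.mu[k]) / self.sigma[k]

    def inverse_transform_at(self, k: int, x: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(x, dtype=float) * self.sigma[k] + self.mu[k]

    @property
    def n_timepoints(self) -> int:
        self._check()
        return self.mu.shape[0]
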