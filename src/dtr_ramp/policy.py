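"""Shared behaviour of fitted linear-regime estimators.

Every learner in this package ends up with per-stage linear decision rules
(:class:`~dtr_ramp.data.DTRCoefficients`) over standardized histories. The
mixin provides the common prediction surface: stagewise decisions on raw
feature matrices (standardization applied internally), in-sample
recommendations, and selected-variable reporting with the |coef| > 1e-6
convention.
"""

from __future__ import annotations

import numpy as np
from sklearn.utils.validation import check_is_fitted

from .data import DTRCoefficients, StageDesign, TrajectoryDataset, sign0

__all__ = ["LinearPolicyMixin"]


class LinearPolicyMixin:
    """Requires fitted attributes ``coef_``, ``design_``, ``scaler_``."""

    selection_threshold: float = 1e-6

    def stage_decision_value(self, t: int, features_raw: np.ndarray) -> np.ndarray:
        """g_t(H_t) for raw (unstandardized) stage-t feature rows."""
        check_is_fitted(self, "coef_")
        h = self.scaler_.transform_stage(t, features_raw)
        d = self.design_
        return (
            h[:, d.penalized[t]] @ self.coef_.beta[t]
            + h[:, d.unpenalized[t]] @ self.coef_.alpha[t]
            + self.coef_.gamma[t]
        )

    def stage_decision(self, t: int, features_raw: np.ndarray) -> np.ndarray:
        """Recommended treatment in {-1, +1} at stage t (sign(0) = +1)."""
        return sign0(self.stage_decision_value(t, features_raw))

    def predict(self, data: TrajectoryDataset) -> np.ndarray:
        """(n, T) recommended treatments along the *observed* histories."""
        check_is_fitted(self, "coef_")
        out = np.empty((data.n, data.T))
        for t in range(data.T):
            out[:, t] = self.stage_decision(t, data.features[t])
        return out

    def decision_function(self, data: TrajectoryDataset) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return np.column_stack(
            [self.stage_decision_value(t, data.features[t]) for t in range(data.T)]
        )

    @property
    def selected_(self):
        """Per-stage boolean masks over the P selection candidates."""
        check_is_fitted(self, "coef_")
        return self.coef_.selected(self.selection_threshold)

    def selected_names(self, data_or_names):
        """Per-stage lists of selected candidate feature names."""
        check_is_fitted(self, "coef_")
        if isinstance(data_or_names, TrajectoryDataset):
            names = data_or_names.column_names
        else:
            names = data_or_names
        out = []
        for t, mask in enumerate(self.selected_):
            cols = [names[t][j] for j in self.design_.penalized[t]]
            out.append([c for c, m in zip(cols, mask) if m])
        return out
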