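"""Hold-out validation metrics: r², RMSE, MAE, MBE.

Errors are defined as e = predicted - observed, so a positive mean bias
error (MBE) means systematic over-prediction. r² is the coefficient of
determination 1 - SS_res/SS_tot; it is undefined (NaN) when the
observations have zero variance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    r2: float
    rmse: float
    mae: float
    mbe: float
    n_test: int

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(predictions, observations) -> MetricsReport:
    """Compute r², RMSE, MAE and MBE for paired prediction/observation vectors.

    The inequality chain rmse >= mae >= |mbe| holds for every input by
    Jensen's inequality and the triangle inequality.
    """
    pred = np.asarray(predictions, dtype=float).ravel()
    obs = np.asarray(observations, dtype=float).ravel()
    if pred.size == 0 or pred.shape != obs.shape:
        raise ValueError("predictions and observations must be nonempty and paired")
    e = pred - obs
    ss_res = float(np.sum(e**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return MetricsReport(
        r2=r2,
        rmse=float(np.sqrt(np.mean(e**2))),
        mae=float(np.mean(np.abs(e))),
        mbe=float(np.mean(e)),
        n_test=int(pred.size),
    )
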