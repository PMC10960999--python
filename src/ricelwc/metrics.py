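"""Model evaluation metrics: coefficient of determination and RMSE.

R^2 is the standard goodness-of-fit form 1 - SSres/SStot (larger is
better); RMSE is sqrt(mean squared error) in the units of the target.
"""

from __future__ import annotations

import numpy as np

from .records import ValidationError


def metrics(observed, predicted) -> dict[str, float]:
    """{'r2': 1 - SSres/SStot, 'rmse': sqrt(SSres/n)} for paired vectors."""
    x = np.asarray(observed, dtype=float)
    xhat = np.asarray(predicted, dtype=float)
    if x.size == 0 or x.size != xhat.size:
        raise ValidationError("observed/predicted must be equal-length and non-empty")
    ss_res = np.sum((x - xhat) ** 2)
    ss_tot = np.sum((x - x.mean()) ** 2)
    if ss_tot == 0:
        raise ValidationError("R^2 undefined: observed values have zero variance")
    return {"r2": float(1.0 - ss_res / ss_tot), "rmse": float(np.sqrt(ss_res / x.size))}
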