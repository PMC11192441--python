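"""Shared result container for all three laterality estimators."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional


@dataclass(frozen=True)
class LiResult:
    """A laterality index with its 95% confidence interval.

    Positive values indicate left-hemisphere dominance.  ``estimate`` is on
    the estimator's native scale: a mean homologous difference score for the
    mirror method (t units), a bounded index in [-1, 1] for the
    threshold-bootstrap method, and a percentage blood-flow difference for
    the Doppler GAM.

    Attributes
    ----------
    estimate : float
        Point estimate of the laterality index.
    ci_low, ci_high : float
        Bounds of the 95% confidence interval.
    method : str
        ``"mirror"``, ``"toolbox"`` or ``"gam"``.
    category : str
        ``"left"``, ``"right"`` or ``"bilateral"``, derived from the CI
        relative to zero (never from the point estimate alone).
    n_units : int
        Number of resampling units behind the estimate: subsamples for the
        mirror method, retained thresholds for the toolbox method, kept
        trials for the GAM.
    seed : int or None
        RNG seed used, when the estimator is stochastic.
    """

    estimate: float
    ci_low: float
    ci_high: float
    method: str
    category: str
    n_units: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    def to_dict(self) -> dict:
        return asdict(self)
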