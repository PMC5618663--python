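"""Common container for fit diagnostics."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class FitResult:
    """Outcome of a least-squares fit: estimates plus convergence diagnostics.

    ``params`` holds the estimated parameters by name; ``rss`` the residual
    sum of squares over ``n_obs`` observations and ``n_params`` free
    parameters.  ``flags`` collects warnings such as rate degeneracy or
    physically implausible estimates; a fit that failed to converge keeps
    ``success=False`` and the optimizer message, never a silent result.
    """

    params: dict
    rss: float
    n_obs: int
    n_params: int
    success: bool
    message: str = ""
    n_iter: int = 0
    flags: list = field(default_factory=list)
    seed: int | None = None

    @property
    def aicc(self) -> float:
        """Small-sample corrected Akaike information criterion (Gaussian RSS form)."""
        import numpy as np

        n, p = self.n_obs, self.n_params
        if n <= p + 1:
            return float("inf")
        rss = max(self.rss, 1e-300)
        return float(n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aicc"] = self.aicc
        return d
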