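"""Result containers shared between inference and IO."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PosteriorSummary:
    """Per-individual posterior summaries plus family-level mutation flags.

    ``individuals`` has one row per individual/marker with at least the
    columns family_id, individual_id, marker_id, mean_cn, p_gain, p_loss,
    p_ins, p_del and the posterior mass columns ``p_cn_<r>``.
    ``family_flags`` has one row per family/threshold with a boolean
    ``flagged`` column (strict ``>`` threshold rule).
    """

    individuals: pd.DataFrame
    family_flags: pd.DataFrame | None = None


@dataclass
class AssociationFit:
    """Posterior summaries for the logistic CNV-disease association model.

    ``table`` mirrors the conventional reporting layout: one row per term
    with posterior mean, posterior SD and P(beta > 0) as a percentage.
    The odds ratio is exp(posterior mean of beta).
    """

    table: pd.DataFrame
    draws: dict[str, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def beta_mean(self) -> float:
        return float(self.table.set_index("term").loc["beta", "mean"])

    @property
    def beta_sd(self) -> float:
        return float(self.table.set_index("term").loc["beta", "sd"])

    @property
    def p_beta_gt0(self) -> float:
        """P(beta > 0) as a fraction in [0, 1]."""
        return float(self.table.set_index("term").loc["beta", "p_gt0_pct"]) / 100.0

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta_mean))

    def beta_interval(self, level: float = 0.90) -> tuple[float, float]:
        """Central posterior credible interval for beta."""
        b = np.asarray(self.draws["beta"]).ravel()
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(b, [lo, 1.0 - lo]))
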