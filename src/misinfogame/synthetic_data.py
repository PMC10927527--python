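"""Synthetic fixtures with known ground truth.

Two generators emulate the structure of the empirical engagement/ratings
data so the statistical pipeline can be validated by parameter recovery
without any external download:

* :func:`generate_site_table` builds a site table (sites x headlines with
  mean accuracy ratings and engagement counts) in which the within-site
  correlation between perceived accuracy and log10-engagement is set by
  type-specific true slopes;

* :func:`generate_rating_table` builds a rating-level table with crossed
  subject and headline random intercepts and a known standardized
  accuracy effect on click/share intentions.

:func:`canned_strategies` returns a small set of named transmitter
strategies with documented qualitative behavior, used across tests and
demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .game_core import TransmitterStrategy

__all__ = [
    "SiteGeneratorSpec",
    "RatingGeneratorSpec",
    "generate_site_table",
    "generate_rating_table",
    "canned_strategies",
]


@dataclass(frozen=True)
class SiteGeneratorSpec:
    """Ground-truth specification of a synthetic site table.

    ``true_slope_*`` are the within-site correlations between perceived
    accuracy and log10-engagement (the quantity the per-site regression
    estimates).  Accuracy ratings are clipped normals on the 1-7 scale,
    with mainstream sites centered higher than misinformation sites but
    overlapping.  ``engagement_log_mean``/``engagement_log_sd`` set the
    location and residual spread of log10 engagement counts.
    """

    n_sites_per_type: int = 20
    headlines_per_site: int = 25
    true_slope_mainstream: float = 0.13
    true_slope_misinfo: float = -0.11
    accuracy_mean_mainstream: float = 4.9
    accuracy_sd_mainstream: float = 0.9
    accuracy_mean_misinfo: float = 3.6
    accuracy_sd_misinfo: float = 0.9
    engagement_log_mean: float = 3.0
    engagement_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.headlines_per_site < 3:
            raise ValueError("headlines_per_site must be >= 3")
        if self.accuracy_sd_mainstream <= 0 or self.accuracy_sd_misinfo <= 0:
            raise ValueError("accuracy sds must be > 0")
        if self.engagement_log_sd < 0:
            raise ValueError("engagement_log_sd must be >= 0")
        for rho in (self.true_slope_mainstream, self.true_slope_misinfo):
            if not (-1.0 < rho < 1.0):
                raise ValueError("true slopes must lie in (-1, 1)")


@dataclass(frozen=True)
class RatingGeneratorSpec:
    """Ground-truth specification of a synthetic rating table.

    ``true_effect`` is the standardized effect of perceived accuracy on the
    click/share outcomes.  The latent outcome is true_effect * z(accuracy)
    plus subject and headline random intercepts and residual noise; when
    subject_sd^2 + headline_sd^2 + noise_sd^2 = 1 - true_effect^2 the
    latent outcome has unit variance and the standardized regression
    coefficient equals ``true_effect`` exactly (up to 1-7 scale clipping).
    """

    n_subjects: int = 100
    n_headlines: int = 40
    true_effect: float = 0.5
    subject_sd: float = 0.5
    headline_sd: float = 0.5
    noise_sd: float = 0.5
    accuracy_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_headlines < 2:
            raise ValueError("need at least 2 subjects and 2 headlines")
        for name in ("subject_sd", "headline_sd", "noise_sd", "accuracy_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _clip17(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 1.0, 7.0)


def generate_site_table(spec: SiteGeneratorSpec) -> pd.DataFrame:
    """Generate a site table with known accuracy-engagement correlations.

    Per site, headline accuracies are drawn from the type's clipped normal;
    log10 engagement is an intercept plus a slope times the within-site
    z-scored accuracy plus residual noise, with the slope chosen so the
    population correlation equals the type's true slope.  Engagement counts
    are rounded powers of ten of the log values.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    settings = {
        "mainstream": (
            spec.true_slope_mainstream,
            spec.accuracy_mean_mainstream,
            spec.accuracy_sd_mainstream,
        ),
        "misinformation": (
            spec.true_slope_misinfo,
            spec.accuracy_mean_misinfo,
            spec.accuracy_sd_misinfo,
        ),
    }
    for site_type, (rho, mu_a, sd_a) in settings.items():
        if spec.engagement_log_sd == 0:
            b = rho  # noiseless: any slope of the right sign gives corr +/-1
        else:
            b = spec.engagement_log_sd * rho / np.sqrt(1.0 - rho**2)
        for s in range(spec.n_sites_per_type):
            site_id = f"{site_type}_{s:03d}"
            acc = _clip17(rng.normal(mu_a, sd_a, size=spec.headlines_per_site))
            z = (acc - acc.mean()) / acc.std() if acc.std() > 0 else np.zeros_like(acc)
            log_eng = (
                spec.engagement_log_mean
                + b * z
                + rng.normal(0.0, spec.engagement_log_sd, size=spec.headlines_per_site)
            )
            eng = np.round(10.0**log_eng).astype(int)
            for h in range(spec.headlines_per_site):
                rows.append(
                    {
                        "site_id": site_id,
                        "site_type": site_type,
                        "headline_id": f"{site_id}_h{h:03d}",
                        "mean_accuracy": acc[h],
                        "engagement": eng[h],
                    }
                )
    return pd.DataFrame(rows)


def generate_rating_table(spec: RatingGeneratorSpec) -> pd.DataFrame:
    """Generate a rating table with crossed subject/headline random effects.

    Every subject rates every headline.  The perceived-accuracy rating has
    a headline-level component plus rater noise (standardized to unit
    variance); click and share outcomes share the same structural formula
    with independent residuals.  Ratings are affinely mapped to the 1-7
    scale and clipped.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nS, nH = spec.n_subjects, spec.n_headlines
    a_h = rng.normal(0.0, 1.0, size=nH)  # headline accuracy signal
    subj_int = rng.normal(0.0, spec.subject_sd, size=nS)
    head_int = rng.normal(0.0, spec.headline_sd, size=nH)
    denom = np.sqrt(1.0 + spec.accuracy_noise_sd**2)
    S, H = np.meshgrid(np.arange(nS), np.arange(nH), indexing="ij")
    z_acc = (a_h[H] + rng.normal(0.0, spec.accuracy_noise_sd, size=(nS, nH))) / denom
    out = {}
    for name in ("click", "share"):
        latent = (
            spec.true_effect * z_acc
            + subj_int[S]
            + head_int[H]
            + rng.normal(0.0, spec.noise_sd, size=(nS, nH))
        )
        out[name] = _clip17(4.0 + latent).ravel()
    return pd.DataFrame(
        {
            "subject_id": np.array([f"s{i:04d}" for i in range(nS)])[S.ravel()],
            "headline_id": np.array([f"h{j:04d}" for j in range(nH)])[H.ravel()],
            "accuracy": _clip17(4.0 + z_acc).ravel(),
            "click": out["click"],
            "share": out["share"],
            "headline_veracity": np.where(a_h[H].ravel() > 0, "true", "false"),
        }
    )


def canned_strategies() -> dict[str, TransmitterStrategy]:
    """Named transmitter strategies with documented qualitative behavior.

    * ``demo_sigmoid`` — sigmoidal feedback, steepness 100, midpoints 0.5
      (after true stories) and 0.25 (after false): true content while
      engagement is low, false once engagement is high, with hysteresis.
    * ``always_true`` — shares only true stories (alpha = beta = 1).
    * ``always_false`` — shares only false stories (alpha = beta = 0).
    * ``no_feedback`` — a fixed mix of true and false stories, independent
      of engagement; enforces no engagement-misinformation correlation.
    * ``responsive_linear`` — a member of the equality-enforcing family
      r+* (alpha = 1, gamma = theta = -beta): pins v_f = v_fc + v_tc, the
      boundary of the responsive-misinformation condition.
    """
    return {
        "demo_sigmoid": TransmitterStrategy.sigmoid(lam=100.0, m_t=0.5, m_f=0.25),
        "always_true": TransmitterStrategy.linear(alpha=1.0, beta=1.0),
        "always_false": TransmitterStrategy.linear(alpha=0.0, beta=0.0),
        "no_feedback": TransmitterStrategy.linear(alpha=0.7, beta=0.4),
        "responsive_linear": TransmitterStrategy.linear(
            alpha=1.0, beta=0.5, gamma=-0.5, theta=-0.5
        ),
    }
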