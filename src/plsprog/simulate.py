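"""Synthetic two-class patient cohorts for end-to-end testing.

The generator emulates a post-prostatectomy cohort split into
non-recurrent and recurrent groups, calibrated to the published group
summaries: ISUP grade group 2.25 +- 0.80 vs 3.1 +- 0.70, pathological-stage
code 2.86 +- 0.71 vs 3.92 +- 0.90, adverse-clinical-features score
1.00 +- 1.18 vs 2.83 +- 1.67, extracapsular-extension positivity 25% vs
75%, seminal-vesicle-invasion 0% vs 33%.

Ordinal variables (ISUP, stage) are drawn by rounding a latent normal and
clipping to 1..5; because rounding plus clipping biases the mean, the
latent mean is solved numerically so the *discretised* expectation hits the
configured target exactly. Adverse flags are Bernoulli with the ECE rate
pinned to its configured value and the remaining flag probabilities solved
to reproduce the configured score mean given the weights; an unreachable
mean raises an infeasibility error rather than silently clipping.

Expression is log2-normal (multiplicative qPCR noise) with a per-gene
class shift on the log2 scale; MALAT1 silenced expression is basal times a
depletion draw. Clinical and molecular variables are independent given the
class — the real cohort's within-group covariance is unknown and not
emulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .clinical_features import AdverseFeatureWeights
from .cohort_io import ClinicalRecord, Cohort
from .expression_features import GENES, RATIO_GENES, ExpressionProfile

__all__ = ["CohortSimParams", "generate_cohort", "generate_null_cohort"]

#: ISUP grade group -> a representative (primary, secondary) Gleason pattern.
_ISUP_TO_GLEASON = {1: (3, 3), 2: (3, 4), 3: (4, 3), 4: (4, 4), 5: (4, 5)}
_STAGE_NAMES = {1: "pT2a", 2: "pT2b", 3: "pT2c", 4: "pT3a", 5: "pT3b"}

# Default per-gene class shifts (log2 fold change, recurrent minus
# non-recurrent) for basal expression. Signs follow the reported component
# correlations: ME3, PDK3, CHKA and MALAT1 higher in recurrent patients,
# pS2 lower; PDK1 and PSA mRNA carry no basal class signal by default.
_DEFAULT_BASAL_EFFECT = {
    "MALAT1": 0.8, "ME3": 0.8, "PDK3": 0.8, "CHKA": 0.8,
    "PS2": -0.6, "PDK1": 0.0, "PSA": 0.0,
}
# Class shifts of the silenced/basal modulation ratio (log2) for the genes
# whose post-silencing modulation was reported as prognostic.
_DEFAULT_RATIO_EFFECT = {"ME3": 0.5, "PDK3": 0.5, "PDK1": 0.5, "PSA": 0.5}


class InfeasibleParamsError(ValueError):
    """The configured group summaries cannot be realised jointly."""


@dataclass
class CohortSimParams:
    """Generator configuration; defaults reproduce the published group summaries.

    Means/sds are (non-recurrent, recurrent) pairs. ``expression_log2_effect``
    shifts recurrent-group basal log2 expression; ``ratio_log2_effect``
    shifts the recurrent-group log2 modulation ratio. MALAT1 depletion is a
    truncated-normal percentage applied to every patient's silenced MALAT1.
    """

    n_nonrecurrent: int = 28
    n_recurrent: int = 12
    isup_mean_sd: tuple[tuple[float, float], tuple[float, float]] = ((2.25, 0.80), (3.1, 0.70))
    stage_mean_sd: tuple[tuple[float, float], tuple[float, float]] = ((2.86, 0.71), (3.92, 0.90))
    adverse_mean_sd: tuple[tuple[float, float], tuple[float, float]] = ((1.00, 1.18), (2.83, 1.67))
    ece_rate: tuple[float, float] = (0.25, 0.75)
    svi_rate: tuple[float, float] = (0.00, 0.33)
    expression_log2_effect: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASAL_EFFECT)
    )
    expression_log2_sd: dict[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in GENES}
    )
    ratio_log2_effect: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RATIO_EFFECT)
    )
    ratio_log2_sd: float = 0.5
    malat1_depletion_mean_sd: tuple[float, float] = (12.0, 25.0)
    age_mean_sd: tuple[float, float] = (66.5, 6.2)
    psa_log_mean_sd: tuple[float, float] = (2.05, 0.45)  # lognormal serum PSA, ng/mL
    weights: AdverseFeatureWeights = field(default_factory=AdverseFeatureWeights)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nonrecurrent < 2 or self.n_recurrent < 2:
            raise ValueError("need at least 2 patients per group")
        for r in (*self.ece_rate, *self.svi_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        for pair in (self.isup_mean_sd, self.stage_mean_sd, self.adverse_mean_sd):
            for _, sd in pair:
                if sd <= 0:
                    raise ValueError("sds must be > 0")


def _discretized_mean(mu: float, sd: float, lo: int = 1, hi: int = 5) -> float:
    """E[clip(round(N(mu, sd)), lo, hi)] in closed form."""
    ks = np.arange(lo, hi + 1)
    uppers = np.concatenate([ks[:-1] + 0.5, [np.inf]])
    lowers = np.concatenate([[-np.inf], ks[:-1] + 0.5])
    probs = stats.norm.cdf(uppers, mu, sd) - stats.norm.cdf(lowers, mu, sd)
    return float((ks * probs).sum())


def _calibrate_latent_mean(target: float, sd: float, lo: int = 1, hi: int = 5) -> float:
    """Latent normal mean whose rounded-and-clipped expectation equals ``target``."""
    if not lo <= target <= hi:
        raise InfeasibleParamsError(f"target mean {target} outside [{lo}, {hi}]")
    f = lambda mu: _discretized_mean(mu, sd, lo, hi) - target
    return float(optimize.brentq(f, lo - 10 * sd, hi + 10 * sd, xtol=1e-12))


def _draw_ordinal(
    rng: np.random.Generator, n: int, target_mean: float, sd: float
) -> np.ndarray:
    mu = _calibrate_latent_mean(target_mean, sd)
    return np.clip(np.round(rng.normal(mu, sd, size=n)), 1, 5).astype(int)


def _solve_flag_probs(
    target_mean: float, ece_rate: float, weights: AdverseFeatureWeights
) -> tuple[float, float, float, float]:
    """Bernoulli probabilities (LVI, margins, ECE, PNI) hitting the score mean.

    ECE is pinned to its configured rate; the remaining mass is spread over
    LVI, margins and PNI with a common probability.
    """
    remaining = target_mean - weights.w_ece * ece_rate
    denom = weights.w_lvi + weights.w_margins + weights.w_pni
    if denom == 0:
        if abs(remaining) > 1e-9:
            raise InfeasibleParamsError("no free flags left to absorb the score mean")
        q = 0.0
    else:
        q = remaining / denom
    if not -1e-9 <= q <= 1 + 1e-9:
        raise InfeasibleParamsError(
            f"adverse score mean {target_mean} unreachable with ECE rate {ece_rate} "
            f"and weights {weights.as_tuple()} (implied flag probability {q:.3f})"
        )
    q = min(max(q, 0.0), 1.0)
    return q, q, ece_rate, q


def generate_cohort(params: CohortSimParams | None = None) -> Cohort:
    """Draw a synthetic cohort; identical parameters give identical cohorts.

    Stage semantics make pT3b and seminal-vesicle invasion the same event;
    if the configured SVI rate is far from the rate implied by the stage
    distribution, a consistency warning is emitted (the stage draw wins).
    """
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed)
    weights = params.weights

    records: list[ClinicalRecord] = []
    expression: dict[str, ExpressionProfile] = {}
    counter = 0
    for group, n in ((0, params.n_nonrecurrent), (1, params.n_recurrent)):
        isup = _draw_ordinal(rng, n, *params.isup_mean_sd[group])
        stage = _draw_ordinal(rng, n, *params.stage_mean_sd[group])
        implied_svi = _discretized_prob_top(params.stage_mean_sd[group])
        if abs(implied_svi - params.svi_rate[group]) > 0.10:
            warnings.warn(
                f"group {group}: configured SVI rate {params.svi_rate[group]:.2f} "
                f"vs {implied_svi:.2f} implied by the stage distribution (pT3b == SVI); "
                "stage draw takes precedence",
                UserWarning,
                stacklevel=2,
            )
        p_flags = _solve_flag_probs(
            params.adverse_mean_sd[group][0], params.ece_rate[group], weights
        )
        flags = rng.random((n, 4)) < np.asarray(p_flags)
        age = np.clip(np.round(rng.normal(*params.age_mean_sd, size=n)), 45, 90).astype(int)
        psa = np.exp(rng.normal(*params.psa_log_mean_sd, size=n))

        for i in range(n):
            counter += 1
            pid = f"S{counter:03d}"
            prim, sec = _ISUP_TO_GLEASON[int(isup[i])]
            ttr = float(np.round(np.exp(rng.normal(2.0, 0.5)), 1)) if group == 1 else None
            records.append(
                ClinicalRecord(
                    patient_id=pid,
                    age=int(age[i]),
                    serum_psa=float(np.round(psa[i], 2)),
                    gleason_primary=prim,
                    gleason_secondary=sec,
                    pathological_stage_raw=f"{_STAGE_NAMES[int(stage[i])]} N0 Mx",
                    lymphovascular_invasion=bool(flags[i, 0]),
                    surgical_margins_positive=bool(flags[i, 1]),
                    extracapsular_extension=bool(flags[i, 2]),
                    perineural_invasion=bool(flags[i, 3]),
                    recurrence=bool(group),
                    time_to_recurrence=max(ttr, 1.0) if ttr is not None else None,
                )
            )
            expression[pid] = _draw_expression(rng, params, group)
    return Cohort(records=records, expression=expression)


def _discretized_prob_top(mean_sd: tuple[float, float], lo: int = 1, hi: int = 5) -> float:
    """P(stage code == hi) under the calibrated discretised normal."""
    mu = _calibrate_latent_mean(mean_sd[0], mean_sd[1], lo, hi)
    return float(1.0 - stats.norm.cdf(hi - 0.5, mu, mean_sd[1]))


def _draw_expression(
    rng: np.random.Generator, params: CohortSimParams, group: int
) -> ExpressionProfile:
    basal: dict[str, float] = {}
    silenced: dict[str, float] = {}
    for gene in GENES:
        eff = params.expression_log2_effect.get(gene, 0.0) * group
        sd = params.expression_log2_sd.get(gene, 1.0)
        basal[gene] = float(2.0 ** rng.normal(eff, sd))
    dep_mu, dep_sd = params.malat1_depletion_mean_sd
    depletion = float(np.clip(rng.normal(dep_mu, dep_sd), -200.0, 99.0))
    silenced["MALAT1"] = basal["MALAT1"] * (1.0 - depletion / 100.0)
    for gene in GENES:
        if gene == "MALAT1":
            continue
        # mild average repression under silencing, plus a class shift of the
        # modulation ratio for the reported "ratio" genes
        shift = -0.3 + params.ratio_log2_effect.get(gene, 0.0) * group
        if gene not in RATIO_GENES:
            shift = -0.3
        silenced[gene] = basal[gene] * float(2.0 ** rng.normal(shift, params.ratio_log2_sd))
    return ExpressionProfile(basal_fc=basal, silenced_fc=silenced)


def generate_null_cohort(
    params: CohortSimParams | None = None, seed: int | None = None
) -> Cohort:
    """Cohort whose labels are independent of every feature.

    All group parameters are equalised to the non-recurrent values and all
    class effects zeroed, so the recurrence label carries no information.
    """
    params = params or CohortSimParams()
    null = replace(
        params,
        isup_mean_sd=(params.isup_mean_sd[0], params.isup_mean_sd[0]),
        stage_mean_sd=(params.stage_mean_sd[0], params.stage_mean_sd[0]),
        adverse_mean_sd=(params.adverse_mean_sd[0], params.adverse_mean_sd[0]),
        ece_rate=(params.ece_rate[0], params.ece_rate[0]),
        svi_rate=(params.svi_rate[0], params.svi_rate[0]),
        expression_log2_effect={g: 0.0 for g in GENES},
        ratio_log2_effect={g: 0.0 for g in RATIO_GENES},
        seed=params.seed if seed is None else seed,
    )
    return generate_cohort(null)
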