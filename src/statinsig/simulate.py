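"""Synthetic two-ancestry statin-response study generator.

Emulates the data layout of an in-vitro statin pharmacotranscriptomics
study: lymphoblastoid cell lines from two ancestry cohorts (European
American and African American), each line incubated with statin and with
control buffer, expression quantified on a variance-stabilized (log2-like)
scale.  High/low responder classes are the tails of each ancestry's plasma
LDL-cholesterol percent-change distribution.

The statin-minus-control expression change of gene g in sample i follows a
linear latent-factor model::

    delta[g, i] = mu_g + beta_g * z_i + sum_k lambda_{gk} * f_{ki}
                  + b_{batch(i), g} + eps_{gi}

where ``z_i`` is +1 for high responders, -1 for low responders and 0
otherwise; ``beta_g = +/- effect_size / 2`` for the planted signature genes
(sign fixed per gene and shared across ancestries) and 0 elsewhere;
``f`` are latent technical confounders with gene loadings
``lambda_{gk} ~ N(0, confounder_loading_sd^2)``; ``b`` is a per-batch
gene-level offset; ``eps`` is Gaussian noise.  The confounders also leak
into the observed covariates (age, sex, smoker, batch), so that principal
components of the delta matrix correlate with covariates until they are
regressed out — the structure the preprocessing stage is designed to remove.

One designated planted gene is coupled to the cellular cholesterol-ester
change, mirroring the in-vitro response marker.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulatedExpression",
    "StudyData",
    "simulate_cohort",
    "simulate_expression",
    "simulate_cholesterol",
    "label_tails",
    "simulate_study",
]

# sub-stream tags so each operation is a pure function of (inputs, seed)
_TAG_COHORT = 1
_TAG_CONFOUNDERS = 2
_TAG_EXPRESSION = 3
_TAG_CHOLESTEROL = 4


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.

    Cohort sizes and the responder-class LDLC percent-change distributions
    default to the clinical characteristics of the emulated study (EA high
    −59.1 ± 3.9 %, EA low −22.2 ± 8.0 %, AA high −57.5 ± 3.2 %, AA low
    −21.5 ± 6.5 %; cohorts 25/25 and 12/14).  Expression-scale parameters
    are free choices on the variance-stabilized scale: unit residual noise,
    a between-class delta shift of ``effect_size`` for planted genes, and
    confounders whose per-gene loadings dominate the noise so that PC
    correction is both necessary and sufficient.
    """

    n_genes: int = 2000
    n_signature: int = 80
    n_ea_high: int = 25
    n_ea_low: int = 25
    n_aa_high: int = 12
    n_aa_low: int = 14
    n_background_samples: int = 54  # EA non-tail samples -> EA totals 104
    effect_size: float = 1.5  # between-class delta shift, in noise_sd units of 1
    n_confounders: int = 3
    confounder_loading_sd: float = 4.0
    covariate_confounder_corr: float = 0.5
    batch_effect_sd: float = 0.5
    noise_sd: float = 1.0
    ce_coupling: float = -0.52
    ce_class_offset: float = 0.0
    ce_noise_sd: float = 1.0
    ce_gene_effect_scale: float = 1.25
    seed: int = 0
    # responder-class LDLC percent-change distributions (mean, sd)
    ea_high_mean: float = -59.1
    ea_high_sd: float = 3.9
    ea_low_mean: float = -22.2
    ea_low_sd: float = 8.0
    aa_high_mean: float = -57.5
    aa_high_sd: float = 3.2
    aa_low_mean: float = -21.5
    aa_low_sd: float = 6.5
    # non-tail samples sit strictly between the tails
    background_low: float = -47.0
    background_high: float = -33.0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_signature", "n_ea_high", "n_ea_low",
                     "n_aa_high", "n_aa_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_background_samples < 0:
            raise ValueError("n_background_samples must be >= 0")
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_confounders < 0:
            raise ValueError("n_confounders must be >= 0")
        for name in ("ea_high_sd", "ea_low_sd", "aa_high_sd", "aa_low_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.ea_high_mean >= self.ea_low_mean:
            raise ValueError("EA classes overlap: high mean must be below low mean")
        if self.aa_high_mean >= self.aa_low_mean:
            raise ValueError("AA classes overlap: high mean must be below low mean")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulatedExpression:
    """Paired control/statin matrices (genes x samples) plus planted truth."""

    control: pd.DataFrame
    statin: pd.DataFrame
    planted_genes: list[str]
    planted_signs: pd.Series  # +1/-1 per planted gene
    ce_gene: str
    ce_gene_biological_delta: pd.Series  # signal + noise, confounder/batch free
    ce_gene_residual_delta: pd.Series  # biological delta minus the class shift

    @property
    def delta(self) -> pd.DataFrame:
        return self.statin - self.control


@dataclass
class StudyData:
    """Full simulated study bundle."""

    config: SimulationConfig
    phenotypes: pd.DataFrame
    expression: SimulatedExpression


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(config.seed), tag)))


def _latent_confounders(config: SimulationConfig, n_samples: int) -> np.ndarray:
    """Latent factors shared between covariates and expression, (K, n)."""
    rng = _rng(config, _TAG_CONFOUNDERS)
    return rng.standard_normal((config.n_confounders, n_samples))


def label_tails(phenotypes: pd.DataFrame, n_high: int, n_low: int,
                ancestry: str) -> pd.DataFrame:
    """Label the LDLC-response tails of one ancestry as high/low responders.

    The ``n_high`` most negative and ``n_low`` least negative
    ``pct_change_ldlc`` samples of that ancestry are labeled ``high`` and
    ``low``; ties are broken by lexicographic ``sample_id``; all other
    samples of the ancestry get ``none``.  Labels of other ancestries are
    left untouched.
    """
    out = phenotypes.copy()
    mask = (out["ancestry"] == ancestry) & np.isfinite(out["pct_change_ldlc"])
    sub = out.loc[mask, ["sample_id", "pct_change_ldlc"]]
    if len(sub) < n_high + n_low:
        raise ValueError(
            f"ancestry {ancestry!r} has {len(sub)} usable samples, "
            f"need {n_high + n_low}")
    out.loc[out["ancestry"] == ancestry, "responder_class"] = "none"
    asc = sub.sort_values(["pct_change_ldlc", "sample_id"],
                          ascending=[True, True])
    high_ids = asc["sample_id"].iloc[:n_high]
    desc = sub.sort_values(["pct_change_ldlc", "sample_id"],
                           ascending=[False, True])
    low_ids = [sid for sid in desc["sample_id"] if sid not in set(high_ids)][:n_low]
    out.loc[out["sample_id"].isin(set(high_ids)), "responder_class"] = "high"
    out.loc[out["sample_id"].isin(set(low_ids)), "responder_class"] = "low"
    return out


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw one two-ancestry cohort phenotype table.

    LDLC percent changes are drawn from the class-calibrated normals (tails)
    and a between-tail uniform (background); responder classes are then
    assigned by tail selection, so tail membership holds by construction.
    Covariates are linked to the latent expression confounders through
    ``covariate_confounder_corr``.
    """
    rng = _rng(config, _TAG_COHORT)
    n_ea = config.n_ea_high + config.n_ea_low + config.n_background_samples
    n_aa = config.n_aa_high + config.n_aa_low
    n = n_ea + n_aa

    sample_id = np.array([f"EA{i + 1:03d}" for i in range(n_ea)]
                         + [f"AA{i + 1:03d}" for i in range(n_aa)])
    ancestry = np.array(["EA"] * n_ea + ["AA"] * n_aa)

    pct = np.concatenate([
        rng.normal(config.ea_high_mean, config.ea_high_sd, config.n_ea_high),
        rng.normal(config.ea_low_mean, config.ea_low_sd, config.n_ea_low),
        rng.uniform(config.background_low, config.background_high,
                    config.n_background_samples),
        rng.normal(config.aa_high_mean, config.aa_high_sd, config.n_aa_high),
        rng.normal(config.aa_low_mean, config.aa_low_sd, config.n_aa_low),
    ])

    f = _latent_confounders(config, n)
    c = float(config.covariate_confounder_corr)
    if not 0.0 <= c <= 1.0:
        raise ValueError("covariate_confounder_corr must be in [0, 1]")
    resid = np.sqrt(max(0.0, 1.0 - c * c))

    def latent(k: int) -> np.ndarray:
        base = f[k % config.n_confounders] if config.n_confounders else 0.0
        return c * base + resid * rng.standard_normal(n) if config.n_confounders \
            else rng.standard_normal(n)

    age = np.clip(np.round(52.0 + 12.0 * latent(0), 1), 25.0, 85.0)
    sex = np.where(latent(1) > 0, "M", "F")
    smoker = np.where(latent(2) > 1.4, "yes", "no")  # ~8% smokers
    batch = np.where(latent(3) > 0, "b1", "b2")

    dll = np.log1p(pct / 100.0)
    noise = rng.standard_normal
    table = pd.DataFrame({
        "sample_id": sample_id,
        "ancestry": ancestry,
        "responder_class": "none",
        "pct_change_ldlc": pct,
        "delta_log_ldlc": dll + 0.02 * noise(n),
        "delta_log_tc": 0.6 * dll + 0.05 * noise(n),
        "delta_log_tg": 0.1 * noise(n),
        "delta_log_hdlc": 0.05 * noise(n),
        "age": age,
        "sex": sex,
        "smoker": smoker,
        "batch": batch,
    })
    table = label_tails(table, config.n_ea_high, config.n_ea_low, "EA")
    table = label_tails(table, config.n_aa_high, config.n_aa_low, "AA")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")
    return table


def simulate_expression(cohort: pd.DataFrame,
                        config: SimulationConfig) -> SimulatedExpression:
    """Draw paired control/statin matrices whose delta follows the factor model."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    classes = set(cohort.loc[cohort["ancestry"] == "EA", "responder_class"])
    if not {"high", "low"} <= classes:
        raise ValueError("discovery ancestry must contain both responder classes")

    rng = _rng(config, _TAG_EXPRESSION)
    g, n = config.n_genes, len(cohort)
    gene_ids = np.array([f"G{i + 1:04d}" for i in range(g)])
    sample_ids = cohort["sample_id"].to_numpy()

    planted_idx = np.sort(rng.choice(g, size=config.n_signature, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_signature)
    signs[0] = 1.0  # the CE-coupled gene: fixed sign, mirrors its real-data analog
    beta = np.zeros(g)
    beta[planted_idx] = signs * config.effect_size / 2.0
    ce_idx = planted_idx[0]
    beta[ce_idx] = config.ce_gene_effect_scale * config.effect_size / 2.0

    z = cohort["responder_class"].map({"high": 1.0, "low": -1.0}).fillna(0.0).to_numpy()
    mu = rng.normal(0.0, 0.3, size=g)

    delta = mu[:, None] + beta[:, None] * z[None, :]
    biological = delta.copy()

    if config.n_confounders:
        f = _latent_confounders(config, n)
        lam = rng.normal(0.0, config.confounder_loading_sd,
                         size=(g, config.n_confounders))
        delta = delta + lam @ f

    levels, level_idx = np.unique(cohort["batch"].to_numpy(), return_inverse=True)
    if config.batch_effect_sd > 0 and len(levels) > 1:
        b = rng.normal(0.0, config.batch_effect_sd, size=(g, len(levels)))
        delta = delta + b[:, level_idx]

    eps = rng.normal(0.0, config.noise_sd, size=(g, n))
    delta = delta + eps
    biological = biological + eps

    base = rng.normal(8.0, 2.0, size=g)
    control = base[:, None] + rng.normal(0.0, 1.0, size=(g, n))
    statin = control + delta

    control_df = pd.DataFrame(control, index=gene_ids, columns=sample_ids)
    statin_df = pd.DataFrame(statin, index=gene_ids, columns=sample_ids)
    planted_genes = list(gene_ids[planted_idx])
    return SimulatedExpression(
        control=control_df,
        statin=statin_df,
        planted_genes=planted_genes,
        planted_signs=pd.Series(np.sign(beta[planted_idx]), index=planted_genes),
        ce_gene=gene_ids[ce_idx],
        ce_gene_biological_delta=pd.Series(biological[ce_idx], index=sample_ids),
        ce_gene_residual_delta=pd.Series(biological[ce_idx] - beta[ce_idx] * z,
                                         index=sample_ids),
    )


def simulate_cholesterol(cohort: pd.DataFrame, planted_gene_delta: pd.Series,
                         config: SimulationConfig
                         ) -> tuple[pd.Series, pd.Series]:
    """Couple the cholesterol-ester change to the designated planted gene.

    ``ce_delta = ce_coupling * standardized(planted_gene_delta)
    + class offset + noise``; ``fc_delta`` (free cholesterol) is pure noise.
    Lipids are assayed in the EA cohort only, with one EA sample unmeasured,
    mirroring the emulated study's n = 103 of 104.
    """
    if len(planted_gene_delta) != len(cohort):
        raise ValueError("planted_gene_delta length does not match cohort")
    x = planted_gene_delta.to_numpy(dtype=float)
    rng = _rng(config, _TAG_CHOLESTEROL)
    sd = x.std()
    xs = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    offset = cohort["responder_class"].map(
        {"high": -config.ce_class_offset, "low": config.ce_class_offset}
    ).fillna(0.0).to_numpy()
    n = len(cohort)
    ce = config.ce_coupling * xs + offset + rng.normal(0.0, config.ce_noise_sd, n)
    fc = rng.normal(0.0, config.ce_noise_sd, n)
    ea = (cohort["ancestry"] == "EA").to_numpy()
    ce = np.where(ea, ce, np.nan)
    fc = np.where(ea, fc, np.nan)
    ea_idx = np.flatnonzero(ea)
    if len(ea_idx) > 1:  # one EA line unmeasured
        drop = rng.choice(ea_idx)
        ce[drop] = np.nan
        fc[drop] = np.nan
    idx = cohort["sample_id"]
    return (pd.Series(ce, index=idx.to_numpy(), name="ce_delta"),
            pd.Series(fc, index=idx.to_numpy(), name="fc_delta"))


def simulate_study(config: SimulationConfig | None = None, *,
                   seed: int | None = None) -> StudyData:
    """Cohort + expression + lipid phenotypes in one deterministic bundle."""
    config = config or SimulationConfig()
    if seed is not None:
        config = config.replace(seed=seed)
    cohort = simulate_cohort(config)
    expr = simulate_expression(cohort, config)
    # CE couples to the gene's within-class (individual) statin response;
    # any class-level CE shift enters separately through ce_class_offset
    ce, fc = simulate_cholesterol(cohort, expr.ce_gene_residual_delta, config)
    cohort = cohort.assign(ce_delta=ce.to_numpy(), fc_delta=fc.to_numpy())
    return StudyData(config=config, phenotypes=cohort, expression=expr)
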