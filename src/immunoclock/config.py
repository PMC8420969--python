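"""Simulation configuration for the synthetic cord-blood cohort generator.

The generator emulates the statistical structure of a 45-sample neonatal
cohort sampled across the gestational-age (GA) continuum (25-41 weeks,
25 term / 20 preterm):

* a GA-dependent logistic-normal cell-subset composition (granulocyte vs
  mononuclear split, then a softmax over 33 mononuclear subsets, with
  per-subset log-linear GA slopes),
* basal signalling levels on the arcsinh scale, linear in GA per
  (subset, protein),
* stimulation-response amplitudes (stimulated minus basal arcsinh level)
  linear in GA per (subset, protein, stimulus),
* five latent per-sample noise factors ("blocks") shared across the
  GA-informative features, inducing correlated feature blocks,
* clinical covariates, independent of the immune features except for the
  steroid-to-birth interval which exists only for preterm deliveries.

Default calibration anchors (term anchor GA0 = 39 w):

* granulocytes are 58% of leukocytes at term falling to ~24.5% below 30 w,
* T lymphocytes are ~47% of leukocytes below 30 w,
* granulocyte frequency correlates with GA at Spearman rho ~ 0.77,
* basal MAP-kinase/NFkB-axis signalling in antigen-presenting cells falls
  with GA while LPS-evoked responses in the same cells rise,
* IFNa-evoked STAT3 (and more weakly STAT1) responses in cytotoxic
  lymphocytes rise with GA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigMismatchError, InvalidConfigError
from .panel import (
    CYTOTOXIC_SUBSETS,
    DEFAULT_PANEL,
    Panel,
)

#: internal RNG seed used to draw the *fixed* uninformative parameter tables;
#: this is part of the default configuration, not of the sampling stream.
_PARAM_SEED = 12345

#: GA anchor (weeks) at which intercept parameters are expressed.
GA_ANCHOR = 39.0

TERM_CUTOFF = 37.0


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# Config container
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Full parameterization of the synthetic cohort generator.

    Attributes
    ----------
    n_samples, n_term : int
        Cohort size and number of term (GA >= ``term_cutoff``) deliveries.
    ga_range_weeks : tuple
        (low, high) bounds of the GA continuum, in weeks.
    events_per_condition : int
        Single-cell events drawn per sample and stimulation condition.
    subset_params : pandas.DataFrame
        One row per subset: ``term_weight`` (granulocytes: leukocyte share
        at the anchor GA; others: unnormalized mononuclear softmax weight),
        ``ga_slope`` (logit / log-weight units per week), ``block`` (latent
        noise factor index, -1 for none), ``block_loading`` and
        ``noise_sd`` (per-sample logit noise).
    basal_params : pandas.DataFrame
        Indexed by (subset, protein): ``term_level`` (arcsinh units at the
        anchor), ``ga_slope`` (arcsinh units/week), ``block``,
        ``block_loading``, ``noise_sd``.
    response_params : pandas.DataFrame
        Indexed by (subset, protein, stimulus); same columns as
        ``basal_params`` with ``term_level`` holding the anchor response
        amplitude.  Only mask-admissible triples appear.
    covariate_params : dict
        Distribution parameters for the clinical covariates.
    event_sd : float
        Event-level spread on the arcsinh scale.
    n_blocks : int
        Number of latent correlated-noise factors.
    seed : int
        Default RNG seed for the sampling stream.
    """

    n_samples: int = 45
    n_term: int = 25
    ga_range_weeks: tuple = (25.0, 41.0)
    term_cutoff: float = TERM_CUTOFF
    ga_anchor: float = GA_ANCHOR
    events_per_condition: int = 5000
    event_sd: float = 0.45
    n_blocks: int = 5
    subset_params: pd.DataFrame = None
    basal_params: pd.DataFrame = None
    response_params: pd.DataFrame = None
    covariate_params: dict = field(default_factory=dict)
    seed: int = 0
    panel: Panel = field(default_factory=lambda: DEFAULT_PANEL, repr=False)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_term > self.n_samples:
            raise InvalidConfigError(
                f"n_term ({self.n_term}) exceeds n_samples ({self.n_samples})"
            )
        lo, hi = self.ga_range_weeks
        if lo < 20.0 or hi > 43.0 or lo >= hi:
            raise InvalidConfigError(
                f"ga_range_weeks {self.ga_range_weeks} outside [20, 43]"
            )
        if self.events_per_condition < 1:
            raise InvalidConfigError("events_per_condition must be >= 1")
        if self.n_blocks < 0:
            raise InvalidConfigError("n_blocks must be >= 0")
        panel = self.panel
        unknown = set(self.subset_params.index) - set(panel.subsets)
        if unknown:
            raise ConfigMismatchError(f"unknown subsets in config: {sorted(unknown)}")
        missing = set(panel.subsets) - set(self.subset_params.index)
        if missing:
            raise InvalidConfigError(f"subsets missing from config: {sorted(missing)}")
        for df, keylen, what in (
            (self.basal_params, 2, "basal_params"),
            (self.response_params, 3, "response_params"),
        ):
            subs = df.index.get_level_values(0)
            prots = df.index.get_level_values(1)
            if not set(subs) <= set(panel.subsets):
                raise ConfigMismatchError(f"{what}: unknown subset(s)")
            if not set(prots) <= set(panel.proteins):
                raise ConfigMismatchError(f"{what}: unknown protein(s)")
        mono = self.subset_params.drop(index="granulocytes", errors="ignore")
        if (mono["term_weight"] <= 0).any():
            raise InvalidConfigError("mononuclear softmax weights must be positive")
        # composition stays a simplex across the GA range (noise-free check)
        g = self.subset_params.loc["granulocytes"]
        for ga in np.linspace(lo, hi, 9):
            share = 1.0 / (1.0 + np.exp(-(g["term_weight_logit"] + g["ga_slope"] * (ga - self.ga_anchor))))
            if not 0.0 < share < 1.0:
                raise InvalidConfigError("granulocyte share leaves (0, 1)")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name not in ("subset_params", "basal_params", "response_params", "panel")
        }
        d["ga_range_weeks"] = list(self.ga_range_weeks)
        d["subset_params"] = self.subset_params.reset_index().to_dict(orient="list")
        d["basal_params"] = self.basal_params.reset_index().to_dict(orient="list")
        d["response_params"] = self.response_params.reset_index().to_dict(orient="list")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        sp = pd.DataFrame(d.pop("subset_params")).set_index("subset")
        bp = pd.DataFrame(d.pop("basal_params")).set_index(["subset", "protein"])
        rp = pd.DataFrame(d.pop("response_params")).set_index(
            ["subset", "protein", "stimulus"]
        )
        d["ga_range_weeks"] = tuple(d["ga_range_weeks"])
        return cls(subset_params=sp, basal_params=bp, response_params=rp, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def copy(self) -> "SimConfig":
        return SimConfig(
            **{
                f.name: (
                    getattr(self, f.name).copy()
                    if isinstance(getattr(self, f.name), (pd.DataFrame, dict))
                    else getattr(self, f.name)
                )
                for f in dataclasses.fields(self)
            }
        )


# ---------------------------------------------------------------------------
# Default parameter tables
# ---------------------------------------------------------------------------

#: term-anchor mononuclear composition (unnormalized softmax weights).
_MONO_WEIGHTS = {
    "cMC": 0.17,
    "intMC": 0.02,
    "ncMC": 0.015,
    "mDC": 0.01,
    "pDC": 0.007,
    "dnDC": 0.003,
    "basophils": 0.01,
    "HSPC": 0.012,
    "NK_CD56dimCD16pos": 0.10,
    "NK_CD56brightCD16neg": 0.015,
    "NK_CD56dimCD16neg": 0.008,
    "ILC": 0.004,
    "B_naive": 0.08,
    "B_memory": 0.012,
    "B_transitional": 0.02,
    "plasmablasts": 0.004,
    "CD4_naive": 0.215,
    "CD4_TCM": 0.03,
    "CD4_TEM": 0.012,
    "CD4_TEMRA": 0.004,
    "CD8_naive": 0.105,
    "CD8_TCM": 0.014,
    "CD8_TEM": 0.009,
    "CD8_TEMRA": 0.008,
    "Treg": 0.025,
    "CD4_CD161pos": 0.016,
    "CD8_CD161pos": 0.014,
    "NKT_like": 0.015,
    "gd_T": 0.02,
    "dn_T": 0.010,
    "CD4_HLADRpos": 0.006,
    "CD8_HLADRpos": 0.005,
    "Tfh_like": 0.013,
}

#: GA-trending subsets: subset -> (slope per week, block, loading, own noise)
_FREQ_TRENDS = {
    # innate defender block: frequencies rise with GA
    "cMC": (0.090, 0, 0.38, 0.15),
    "NK_CD56dimCD16pos": (0.050, 0, 0.30, 0.15),
    # regulatory / invariant T block: frequencies fall with GA
    "Treg": (-0.075, 1, 0.30, 0.18),
    "CD4_CD161pos": (-0.080, 1, 0.30, 0.18),
    "CD8_CD161pos": (-0.085, 1, 0.30, 0.18),
    "NKT_like": (-0.080, 1, 0.30, 0.18),
}

#: granulocyte leukocyte-share anchors: 58% at the 39 w anchor, 24.5% at 27.5 w.
_GRANU_TERM_SHARE = 0.58
_GRANU_LOW_SHARE = 0.245
_GRANU_LOW_GA = 27.5
_GRANU_BLOCK = 0
_GRANU_LOADING = 0.44
_GRANU_NOISE = 0.12

#: basal MAP-kinase/NFkB-axis tone falls with GA in antigen-presenting
#: cells.  The whole pathway block shares one GA-loaded latent factor; a
#: per-feature strength jitter scales GA slope and factor loading together,
#: keeping the block an (approximately) one-factor structure with dense
#: within-block correlation, as in real cytometry features.
_APC_SUBSETS = ("mDC", "pDC", "cMC", "intMC", "ncMC")
_BASAL_TREND_PROTEINS = {
    "pMAPKAPK2": 1.65,
    "pS6": 1.45,
    "pP38": 1.55,
    "pNFkB": 1.75,
    "pERK12": 1.50,
    "pCREB": 1.60,
}
_BASAL_SUBSET_OFFSET = {"cMC": 0.10, "intMC": 0.0, "ncMC": -0.10, "mDC": 0.05, "pDC": -0.05}
_BASAL_SLOPE = -0.050
_BASAL_BLOCK = 2
_BASAL_LOADING = 0.30
_BASAL_NOISE = 0.11

#: LPS-evoked MAP-kinase/NFkB responses rise with GA in monocytic APCs
#: (weaker, sub-significant trend in non-classical monocytes).
_LPS_TREND_SUBSETS = ("mDC", "cMC", "intMC", "ncMC")
_LPS_SUBSET_SCALE = {"mDC": 1.0, "cMC": 1.0, "intMC": 0.95, "ncMC": 0.85}
_LPS_TREND_PROTEINS = {
    "pMAPKAPK2": 1.45,
    "pP38": 1.35,
    "pNFkB": 1.30,
    "pERK12": 1.30,
    "pS6": 1.25,
    "pCREB": 1.25,
}
_LPS_SLOPE = 0.042
_LPS_BLOCK = 3
_LPS_LOADING = 0.33
_LPS_NOISE = 0.12

#: IFNa-evoked STAT responses rise with GA in cytotoxic lymphocytes
#: (STAT3 most prominently; STAT1 in the same cells, less pronounced).
_IFNA_EXTRA_SUBSETS = ("CD8_naive", "gd_T", "NK_CD56dimCD16neg")
_IFNA_TREND = {
    "pSTAT3": dict(amp=1.30, slope=0.050, loading=0.29, noise=0.11),
    "pSTAT1": dict(amp=1.15, slope=0.032, loading=0.26, noise=0.09),
}
_IFNA_EXTRA_PROTEINS = ("pSTAT3",)
_IFNA_BLOCK = 4

#: multiplicative jitter on (slope, loading) of signalling trend features.
_STRENGTH_JITTER = (0.95, 1.2)

_DEFAULT_COVARIATES = {
    "sex": {"p_female": 0.5},
    "steroid_interval_h": {"log_mean": 3.9, "log_sd": 0.9},
    "rom_duration_h": {"p_zero": 0.45, "log_mean": 2.1, "log_sd": 1.0},
    "labor_duration_h": {"p_zero": 0.30, "log_mean": 2.2, "log_sd": 0.8},
    "gdm": {"p": 0.12},
    "hba1c_pct": {"mean": 5.1, "sd": 0.35},
    "preeclampsia": {"p_term": 0.08, "p_preterm": 0.30},
    "severe_preeclampsia": {"p_given_pe_term": 0.2, "p_given_pe_preterm": 0.5},
    "gbs": {"p_pos": 0.22, "p_unknown": 0.12},
}


def _default_subset_params(panel: Panel) -> pd.DataFrame:
    rows = []
    granu_slope = (_logit(_GRANU_TERM_SHARE) - _logit(_GRANU_LOW_SHARE)) / (
        GA_ANCHOR - _GRANU_LOW_GA
    )
    for subset in panel.subsets:
        if subset == "granulocytes":
            rows.append(
                dict(
                    subset=subset,
                    term_weight=_GRANU_TERM_SHARE,
                    term_weight_logit=_logit(_GRANU_TERM_SHARE),
                    ga_slope=granu_slope,
                    block=_GRANU_BLOCK,
                    block_loading=_GRANU_LOADING,
                    noise_sd=_GRANU_NOISE,
                )
            )
            continue
        slope, block, loading, noise = _FREQ_TRENDS.get(subset, (0.0, -1, 0.0, 0.45))
        w = _MONO_WEIGHTS[subset]
        rows.append(
            dict(
                subset=subset,
                term_weight=w,
                term_weight_logit=float(np.log(w)),
                ga_slope=slope,
                block=block,
                block_loading=loading,
                noise_sd=noise,
            )
        )
    return pd.DataFrame(rows).set_index("subset")


def _default_basal_params(panel: Panel, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for subset in panel.subsets:
        for protein in panel.proteins:
            if subset in _APC_SUBSETS and protein in _BASAL_TREND_PROTEINS:
                strength = float(rng.uniform(*_STRENGTH_JITTER))
                rows.append(
                    dict(
                        subset=subset,
                        protein=protein,
                        term_level=_BASAL_TREND_PROTEINS[protein]
                        + _BASAL_SUBSET_OFFSET[subset],
                        ga_slope=_BASAL_SLOPE * strength,
                        block=_BASAL_BLOCK,
                        block_loading=_BASAL_LOADING * strength,
                        noise_sd=_BASAL_NOISE,
                    )
                )
            else:
                rows.append(
                    dict(
                        subset=subset,
                        protein=protein,
                        term_level=float(rng.uniform(0.3, 1.2)),
                        ga_slope=0.0,
                        block=-1,
                        block_loading=0.0,
                        noise_sd=float(rng.uniform(0.12, 0.28)),
                    )
                )
    return pd.DataFrame(rows).set_index(["subset", "protein"])


def _default_response_params(
    panel: Panel, mask: dict, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for subset in panel.subsets:
        for protein in panel.proteins:
            for stim in panel.stimuli:
                if not mask[(subset, protein, stim)]:
                    continue
                if (
                    stim == "LPS"
                    and subset in _LPS_TREND_SUBSETS
                    and protein in _LPS_TREND_PROTEINS
                ):
                    strength = _LPS_SUBSET_SCALE[subset] * float(
                        rng.uniform(*_STRENGTH_JITTER)
                    )
                    rows.append(
                        dict(
                            subset=subset,
                            protein=protein,
                            stimulus=stim,
                            term_level=_LPS_TREND_PROTEINS[protein],
                            ga_slope=_LPS_SLOPE * strength,
                            block=_LPS_BLOCK,
                            block_loading=_LPS_LOADING * strength,
                            noise_sd=_LPS_NOISE,
                        )
                    )
                elif (
                    stim == "IFNa"
                    and (
                        (subset in CYTOTOXIC_SUBSETS and protein in _IFNA_TREND)
                        or (
                            subset in _IFNA_EXTRA_SUBSETS
                            and protein in _IFNA_EXTRA_PROTEINS
                        )
                    )
                ):
                    t = _IFNA_TREND[protein]
                    strength = float(rng.uniform(*_STRENGTH_JITTER))
                    if subset in _IFNA_EXTRA_SUBSETS:
                        strength *= 0.85
                    rows.append(
                        dict(
                            subset=subset,
                            protein=protein,
                            stimulus=stim,
                            term_level=t["amp"],
                            ga_slope=t["slope"] * strength,
                            block=_IFNA_BLOCK,
                            block_loading=t["loading"] * strength,
                            noise_sd=t["noise"],
                        )
                    )
                else:
                    rows.append(
                        dict(
                            subset=subset,
                            protein=protein,
                            stimulus=stim,
                            term_level=float(rng.uniform(0.05, 0.5)),
                            ga_slope=0.0,
                            block=-1,
                            block_loading=0.0,
                            noise_sd=float(rng.uniform(0.12, 0.30)),
                        )
                    )
    return pd.DataFrame(rows).set_index(["subset", "protein", "stimulus"])


def default_config(seed: int = 0, events_per_condition: int = 5000) -> SimConfig:
    """Build the default, calibrated simulation configuration.

    The uninformative (zero-slope) parameter entries are drawn once from a
    fixed internal RNG so that the default configuration is identical across
    calls; ``seed`` only controls the sampling stream.
    """
    from .panel import default_penalization_mask

    panel = DEFAULT_PANEL
    prng = np.random.default_rng(_PARAM_SEED)
    mask = default_penalization_mask(panel)
    cfg = SimConfig(
        events_per_condition=events_per_condition,
        subset_params=_default_subset_params(panel),
        basal_params=_default_basal_params(panel, prng),
        response_params=_default_response_params(panel, mask, prng),
        covariate_params=dict(_DEFAULT_COVARIATES),
        seed=seed,
        panel=panel,
    )
    cfg.validate()
    return cfg


def null_config(seed: int = 0, events_per_condition: int = 5000) -> SimConfig:
    """Default configuration with every GA slope zeroed (null generator).

    Under this configuration no feature carries GA information; the latent
    noise blocks and all dispersion parameters are retained.
    """
    cfg = default_config(seed=seed, events_per_condition=events_per_condition)
    cfg.subset_params = cfg.subset_params.assign(ga_slope=0.0)
    cfg.basal_params = cfg.basal_params.assign(ga_slope=0.0)
    cfg.response_params = cfg.response_params.assign(ga_slope=0.0)
    return cfg
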