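"""Synthetic cohort and single-cell event generation.

`generate_cohort` draws gestational ages and clinical covariates for a
term/preterm-stratified cohort; `simulate_events` draws population-labelled
single-cell marker intensities per sample and stimulation condition with the
generative structure described in :mod:`immunoclock.config`;
`ground_truth_features` returns the identifiers of the features whose
generating parameters carry a nonzero GA slope, for recovery testing.

GA values are drawn with stratified ("jittered grid") uniform sampling
within each stratum: stratum positions are evenly spaced and each is
jittered uniformly within its cell.  The marginal distribution is uniform on
the stratum, while the realized cohort reliably covers the whole GA range —
in particular, the default preterm stratum always contains samples below
30 weeks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import InvalidConfigError
from .panel import CONDITIONS, STIMULI, UNSTIM

__all__ = [
    "generate_cohort",
    "simulate_events",
    "ground_truth_features",
    "feature_id",
    "write_events",
    "read_events",
    "write_cohort",
    "read_cohort",
]

COVARIATE_COLUMNS = [
    "sex",
    "steroid_interval_h",
    "rom_duration_h",
    "labor_duration_h",
    "gdm",
    "hba1c_pct",
    "preeclampsia",
    "severe_preeclampsia",
    "gbs",
]


def feature_id(feature_class: str, subset: str, protein: str | None = None,
               stimulus: str | None = None) -> str:
    """Canonical feature identifier.

    ``freq_<subset>``, ``basal_<subset>_<protein>``, or
    ``resp_<stimulus>_<subset>_<protein>``.
    """
    if feature_class == "frequency":
        return f"freq_{subset}"
    if feature_class == "basal":
        return f"basal_{subset}_{protein}"
    if feature_class == "response":
        return f"resp_{stimulus}_{subset}_{protein}"
    raise ValueError(f"unknown feature class {feature_class!r}")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def _stratified_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    """Jittered evenly spaced draws: uniform marginal, low-discrepancy spread."""
    if n == 0:
        return np.empty(0)
    u = rng.uniform(size=n)
    return lo + (hi - lo) * (np.arange(n) + u) / n


def generate_cohort(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table of gestational ages and clinical covariates.

    Returns one row per sample with ``ga_weeks``, a ``term`` flag
    (GA >= ``config.term_cutoff``) and the clinical covariates.  The
    steroid-to-birth interval is defined for every preterm sample and
    missing (NaN) for every term sample, mirroring universal antenatal
    steroid exposure before 37 weeks and none at term.  GBS status may be
    unknown (NaN).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.ga_range_weeks
    n_term = config.n_term
    n_pre = config.n_samples - n_term
    if hi <= config.term_cutoff and n_term > 0:
        raise InvalidConfigError("ga_range_weeks excludes the term stratum")

    ga_term = _stratified_uniform(rng, config.term_cutoff, hi, n_term)
    ga_pre = _stratified_uniform(rng, lo, min(config.term_cutoff, hi) - 1e-9, n_pre)
    ga = np.concatenate([ga_term, ga_pre])
    term = ga >= config.term_cutoff

    cp = config.covariate_params
    n = config.n_samples
    sex = rng.uniform(size=n) < cp["sex"]["p_female"]

    steroid = np.full(n, np.nan)
    sp = cp["steroid_interval_h"]
    steroid[~term] = np.exp(rng.normal(sp["log_mean"], sp["log_sd"], (~term).sum()))

    def _zero_inflated_lognormal(p):
        vals = np.exp(rng.normal(p["log_mean"], p["log_sd"], n))
        vals[rng.uniform(size=n) < p["p_zero"]] = 0.0
        return vals

    rom = _zero_inflated_lognormal(cp["rom_duration_h"])
    labor = _zero_inflated_lognormal(cp["labor_duration_h"])
    gdm = rng.uniform(size=n) < cp["gdm"]["p"]
    hba1c = rng.normal(cp["hba1c_pct"]["mean"], cp["hba1c_pct"]["sd"], n)

    pe_p = np.where(term, cp["preeclampsia"]["p_term"], cp["preeclampsia"]["p_preterm"])
    pe = rng.uniform(size=n) < pe_p
    sev_p = np.where(
        term,
        cp["severe_preeclampsia"]["p_given_pe_term"],
        cp["severe_preeclampsia"]["p_given_pe_preterm"],
    )
    severe = pe & (rng.uniform(size=n) < sev_p)

    g = cp["gbs"]
    u = rng.uniform(size=n)
    gbs = np.where(u < g["p_unknown"], np.nan, (u < g["p_unknown"] + g["p_pos"]).astype(float))

    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:02d}" for i in range(n)],
            "ga_weeks": ga,
            "term": term,
            "sex": sex.astype(int),
            "steroid_interval_h": steroid,
            "rom_duration_h": rom,
            "labor_duration_h": labor,
            "gdm": gdm.astype(int),
            "hba1c_pct": hba1c,
            "preeclampsia": pe.astype(int),
            "severe_preeclampsia": severe.astype(int),
            "gbs": gbs,
        }
    )
    return cohort


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------


def _composition_probabilities(
    config: SimConfig, ga: np.ndarray, eta: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample subset probabilities over the full 34-subset simplex."""
    panel = config.panel
    sp = config.subset_params.loc[list(panel.subsets)]
    n = ga.size
    dga = ga - config.ga_anchor

    g = sp.loc["granulocytes"]
    block = int(g["block"])
    lg = (
        g["term_weight_logit"]
        + g["ga_slope"] * dga
        + (g["block_loading"] * eta[:, block] if block >= 0 else 0.0)
        + g["noise_sd"] * rng.standard_normal(n)
    )
    p_granu = 1.0 / (1.0 + np.exp(-lg))

    mono = sp.drop(index="granulocytes")
    logw = (
        mono["term_weight_logit"].to_numpy()[None, :]
        + np.outer(dga, mono["ga_slope"].to_numpy())
        + mono["noise_sd"].to_numpy()[None, :] * rng.standard_normal((n, len(mono)))
    )
    blocks = mono["block"].to_numpy().astype(int)
    loaded = blocks >= 0
    logw[:, loaded] += eta[:, blocks[loaded]] * mono["block_loading"].to_numpy()[loaded]
    w = np.exp(logw - logw.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)

    probs = np.empty((n, len(panel.subsets)))
    subset_index = {s: j for j, s in enumerate(panel.subsets)}
    probs[:, subset_index["granulocytes"]] = p_granu
    for j, s in enumerate(mono.index):
        probs[:, subset_index[s]] = (1.0 - p_granu) * w[:, j]
    return probs


def _signal_means(
    config: SimConfig, ga: np.ndarray, eta: np.ndarray, rng: np.random.Generator
):
    """Per-sample arcsinh-scale location parameters.

    Returns ``basal`` of shape (n, n_subsets, n_proteins) and ``amp`` of
    shape (n, n_subsets, n_proteins, n_stimuli); ``amp`` is zero where no
    response parameter is configured (the stimulated distribution then
    equals the basal one).
    """
    panel = config.panel
    n = ga.size
    dga = ga - config.ga_anchor
    ns, npr = len(panel.subsets), len(panel.proteins)
    s_idx = {s: i for i, s in enumerate(panel.subsets)}
    p_idx = {p: i for i, p in enumerate(panel.proteins)}
    st_idx = {s: i for i, s in enumerate(panel.stimuli)}

    def _draw(df, shape, keyfun):
        level = np.zeros(shape)
        out = np.zeros((n,) + shape)
        slope = np.zeros(shape)
        loading = np.zeros(shape)
        noise = np.zeros(shape)
        block = np.full(shape, -1, dtype=int)
        for key, row in df.iterrows():
            ix = keyfun(key)
            level[ix] = row["term_level"]
            slope[ix] = row["ga_slope"]
            loading[ix] = row["block_loading"]
            noise[ix] = row["noise_sd"]
            block[ix] = int(row["block"])
        out += level[None]
        out += np.multiply.outer(dga, slope)
        loaded = block >= 0
        if loaded.any():
            out[:, loaded] += eta[:, block[loaded]] * loading[loaded][None, :]
        out += noise[None] * rng.standard_normal((n,) + shape)
        return out

    basal = _draw(
        config.basal_params, (ns, npr), lambda k: (s_idx[k[0]], p_idx[k[1]])
    )
    amp = _draw(
        config.response_params,
        (ns, npr, len(panel.stimuli)),
        lambda k: (s_idx[k[0]], p_idx[k[1]], st_idx[k[2]]),
    )
    return basal, amp


def simulate_events(
    cohort: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw population-labelled single-cell events for every sample/condition.

    For each sample, a latent composition over the 34 subsets (logistic-
    normal, linear in GA on the logit scale) is drawn once and shared by all
    four conditions; subset counts are multinomial with
    ``events_per_condition`` trials.  Marker intensities are
    ``5 * sinh(z)`` with ``z ~ Normal(mu, event_sd)`` truncated at zero ion
    counts, so the arcsinh-median of the generated intensities equals the
    configured location ``mu`` (basal level, plus the response amplitude
    under stimulation).

    Returns a tidy event table: one row per cell with ``sample_id``,
    ``condition``, ``subset`` and one intensity column per protein.
    """
    config.validate()
    if len(cohort) < 1:
        raise InvalidConfigError("cohort must contain at least one sample")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    panel = config.panel
    ga = cohort["ga_weeks"].to_numpy(float)
    n = ga.size

    eta = rng.standard_normal((n, max(config.n_blocks, 1)))
    probs = _composition_probabilities(config, ga, eta, rng)
    basal, amp = _signal_means(config, ga, eta, rng)

    counts = np.empty((n, len(CONDITIONS), len(panel.subsets)), dtype=np.int64)
    for i in range(n):
        for c in range(len(CONDITIONS)):
            counts[i, c] = rng.multinomial(config.events_per_condition, probs[i])

    sample_ids = cohort["sample_id"].to_numpy()
    frames = []
    subset_arr = np.asarray(panel.subsets, dtype=object)
    for i in range(n):
        for c, cond in enumerate(CONDITIONS):
            cnt = counts[i, c]
            codes = np.repeat(np.arange(len(panel.subsets)), cnt)
            mu = basal[i, codes, :]
            if cond != UNSTIM:
                mu = mu + amp[i, codes, :, c - 1]
            z = mu + config.event_sd * rng.standard_normal(mu.shape)
            intensities = np.maximum(5.0 * np.sinh(z), 0.0).astype(np.float32)
            df = pd.DataFrame(intensities, columns=list(panel.proteins))
            df.insert(0, "subset", subset_arr[codes])
            df.insert(0, "condition", cond)
            df.insert(0, "sample_id", sample_ids[i])
            frames.append(df)
    events = pd.concat(frames, ignore_index=True)
    events["sample_id"] = events["sample_id"].astype("category")
    events["condition"] = pd.Categorical(events["condition"], categories=CONDITIONS)
    events["subset"] = pd.Categorical(events["subset"], categories=panel.subsets)
    return events


def ground_truth_features(config: SimConfig) -> set[str]:
    """Identifiers of features whose generating parameters depend on GA.

    A feature is ground-truth informative iff its configured GA slope is
    nonzero.  Latent block loadings alone (correlated noise) do not make a
    feature informative.
    """
    out: set[str] = set()
    for subset, row in config.subset_params.iterrows():
        if row["ga_slope"] != 0.0:
            out.add(feature_id("frequency", subset))
    for (subset, protein), row in config.basal_params.iterrows():
        if row["ga_slope"] != 0.0:
            out.add(feature_id("basal", subset, protein))
    for (subset, protein, stim), row in config.response_params.iterrows():
        if row["ga_slope"] != 0.0:
            out.add(feature_id("response", subset, protein, stim))
    return out


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------


def write_events(events: pd.DataFrame, path) -> None:
    """Write an event table as (optionally gzip-compressed) CSV."""
    events.to_csv(path, index=False)


def read_events(path, panel=None) -> pd.DataFrame:
    from .panel import DEFAULT_PANEL

    panel = panel or DEFAULT_PANEL
    events = pd.read_csv(path)
    events["sample_id"] = events["sample_id"].astype("category")
    events["condition"] = pd.Categorical(events["condition"], categories=CONDITIONS)
    events["subset"] = pd.Categorical(events["subset"], categories=panel.subsets)
    return events


def write_cohort(cohort: pd.DataFrame, path, na_rep: str = "NA") -> None:
    cohort.to_csv(path, index=False, na_rep=na_rep)


def read_cohort(path, na_values: str = "NA") -> pd.DataFrame:
    return pd.read_csv(path, na_values=[na_values])
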