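"""Immune feature extraction from population-labelled single-cell events.

Three feature classes are computed per sample:

* **frequency** — subset abundance, in percent.  All subsets are expressed
  as a percentage of singlet live mononuclear cells, except granulocytes,
  which are expressed as a percentage of singlet live leukocytes.  Only the
  unstimulated condition contributes.
* **basal** — arcsinh of the median ion-count intensity, ``asinh(median/5)``,
  of a signalling protein over a subset's unstimulated events.
* **response** — the stimulated-minus-unstimulated difference of the
  arcsinh-median for a (subset, protein, stimulus) triple.  Only triples
  admitted by the knowledge-based penalization mask are emitted.

Empty populations yield missing values; features missing in more than
``max_missing_frac`` of samples are dropped and the remaining missing
entries are imputed with the feature median, keeping the matrix complete
for penalized regression while flagging sparse populations in the
provenance attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyPopulationError,
    IncompleteSampleError,
    UndefinedFrequencyError,
)
from .panel import CONDITIONS, DEFAULT_PANEL, Panel, UNSTIM, default_penalization_mask
from .simulate import feature_id

__all__ = [
    "arcsinh_median",
    "compute_frequency",
    "compute_basal",
    "compute_response",
    "assemble_features",
    "FeatureMatrix",
]

ARCSINH_COFACTOR = 5.0


def arcsinh_median(values, cofactor: float = ARCSINH_COFACTOR) -> float:
    """``asinh(median(values) / cofactor)``.

    The median of an even-length vector is the midpoint of the two central
    order statistics.  Raises :class:`EmptyPopulationError` on empty input.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyPopulationError("cannot take arcsinh-median of an empty population")
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return float(np.arcsinh(np.median(values) / cofactor))


@dataclass
class FeatureMatrix:
    """Samples x immune-features value grid with per-feature annotations.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows indexed by sample id, columns by feature id.  Frequencies in
        percent, basal features in arcsinh units, responses in
        arcsinh-difference units.
    defs : pandas.DataFrame
        One row per feature (indexed by feature id) with ``feature_class``
        (frequency/basal/response), ``cell_type``, ``protein`` and
        ``stimulus`` (empty string where not applicable).
    dropped : list
        Feature ids removed because they were missing in too many samples.
    imputed : dict
        feature id -> number of imputed sample values.
    """

    values: pd.DataFrame
    defs: pd.DataFrame
    dropped: list = field(default_factory=list)
    imputed: dict = field(default_factory=dict)

    @property
    def sample_ids(self):
        return list(self.values.index)

    @property
    def feature_ids(self):
        return list(self.values.columns)

    def subset(self, feature_ids) -> "FeatureMatrix":
        feature_ids = [f for f in feature_ids if f in self.values.columns]
        return FeatureMatrix(
            values=self.values[feature_ids].copy(),
            defs=self.defs.loc[feature_ids].copy(),
            dropped=list(self.dropped),
            imputed={k: v for k, v in self.imputed.items() if k in feature_ids},
        )

    def classes(self) -> pd.Series:
        """feature id -> feature class."""
        return self.defs["feature_class"]

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    def defs_to_json(self, path) -> None:
        self.defs.reset_index().to_json(path, orient="records", indent=1)

    @classmethod
    def from_frames(cls, values: pd.DataFrame, defs: pd.DataFrame) -> "FeatureMatrix":
        return cls(values=values, defs=defs.loc[values.columns])


def _lineage_masks(events: pd.DataFrame, panel: Panel):
    """Boolean leukocyte / mononuclear masks derived from the subset label."""
    is_leuk = np.ones(len(events), dtype=bool)
    non_mono = events["subset"].isin(panel.non_mononuclear).to_numpy()
    return is_leuk, ~non_mono


def compute_frequency(
    events: pd.DataFrame, sample_id, subset: str, panel: Panel = DEFAULT_PANEL
) -> float:
    """Subset frequency (percent) in the unstimulated condition.

    Granulocytes (and any other non-mononuclear subset) are referenced to
    all leukocyte events; every other subset to mononuclear events.
    """
    panel.validate_subset(subset)
    sel = (events["sample_id"] == sample_id) & (events["condition"] == UNSTIM)
    ev = events.loc[sel]
    if len(ev) == 0:
        raise UndefinedFrequencyError(f"sample {sample_id!r} has no unstim events")
    numer = int((ev["subset"] == subset).sum())
    if panel.is_mononuclear(subset):
        denom = int((~ev["subset"].isin(panel.non_mononuclear)).sum())
    else:
        denom = len(ev)
    if denom == 0:
        raise UndefinedFrequencyError(
            f"zero denominator for subset {subset!r} in sample {sample_id!r}"
        )
    return 100.0 * numer / denom


def compute_basal(
    events: pd.DataFrame, sample_id, subset: str, protein: str,
    panel: Panel = DEFAULT_PANEL,
) -> float:
    """Basal signalling: arcsinh-median intensity over unstimulated events."""
    panel.validate_subset(subset)
    panel.validate_protein(protein)
    sel = (
        (events["sample_id"] == sample_id)
        & (events["condition"] == UNSTIM)
        & (events["subset"] == subset)
    )
    return arcsinh_median(events.loc[sel, protein].to_numpy())


def compute_response(
    events: pd.DataFrame, sample_id, subset: str, protein: str, stimulus: str,
    panel: Panel = DEFAULT_PANEL,
) -> float:
    """Stimulation response: stimulated minus unstimulated arcsinh-median."""
    panel.validate_subset(subset)
    panel.validate_protein(protein)
    if stimulus not in panel.stimuli:
        raise ValueError(f"unknown stimulus {stimulus!r}")
    base = compute_basal(events, sample_id, subset, protein, panel)
    sel = (
        (events["sample_id"] == sample_id)
        & (events["condition"] == stimulus)
        & (events["subset"] == subset)
    )
    stim = arcsinh_median(events.loc[sel, protein].to_numpy())
    return stim - base


def assemble_features(
    events: pd.DataFrame,
    panel: Panel = DEFAULT_PANEL,
    mask: dict | None = None,
    max_missing_frac: float = 0.2,
    cofactor: float = ARCSINH_COFACTOR,
) -> FeatureMatrix:
    """Build the full sample x feature matrix from an event table.

    Column order is deterministic: the frequency block (panel subset
    order), then the basal block (subset-major, protein order), then the
    response block (stimulus, subset, protein order, mask-admitted triples
    only).

    Raises :class:`IncompleteSampleError` if any sample lacks one of the
    four conditions.
    """
    if mask is None:
        mask = default_penalization_mask(panel)

    samples = list(pd.unique(events["sample_id"]))
    present = events.groupby("sample_id", observed=True)["condition"].agg(
        lambda s: frozenset(s.unique())
    )
    incomplete = [s for s in samples if not set(CONDITIONS) <= set(present.get(s, ()))]
    if incomplete:
        raise IncompleteSampleError(
            f"samples missing conditions: {sorted(map(str, incomplete))}"
        )

    # per-(sample, condition, subset) medians of every marker, then arcsinh
    med = (
        events.groupby(["sample_id", "condition", "subset"], observed=False)[
            list(panel.proteins)
        ]
        .median()
    )
    arc = np.arcsinh(med / cofactor)

    # per-(sample, condition, subset) event counts
    cnt = events.groupby(["sample_id", "condition", "subset"], observed=False).size()

    unstim_cnt = cnt.xs(UNSTIM, level="condition").unstack("subset").reindex(
        index=samples, columns=list(panel.subsets), fill_value=0
    )
    leuk = unstim_cnt.sum(axis=1)
    mono_cols = [s for s in panel.subsets if panel.is_mononuclear(s)]
    mono = unstim_cnt[mono_cols].sum(axis=1)

    cols: dict[str, pd.Series] = {}
    defs_rows = []

    for subset in panel.subsets:
        denom = mono if panel.is_mononuclear(subset) else leuk
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = 100.0 * unstim_cnt[subset] / denom.replace(0, np.nan)
        fid = feature_id("frequency", subset)
        cols[fid] = freq
        defs_rows.append(
            dict(feature_id=fid, feature_class="frequency", cell_type=subset,
                 protein="", stimulus="")
        )

    arc_unstim = arc.xs(UNSTIM, level="condition")
    for subset in panel.subsets:
        for protein in panel.proteins:
            fid = feature_id("basal", subset, protein)
            s = arc_unstim.xs(subset, level="subset")[protein].reindex(samples)
            cols[fid] = s
            defs_rows.append(
                dict(feature_id=fid, feature_class="basal", cell_type=subset,
                     protein=protein, stimulus="")
            )

    for stim in panel.stimuli:
        arc_stim = arc.xs(stim, level="condition")
        for subset in panel.subsets:
            base = arc_unstim.xs(subset, level="subset").reindex(samples)
            stim_vals = arc_stim.xs(subset, level="subset").reindex(samples)
            for protein in panel.proteins:
                if not mask.get((subset, protein, stim), False):
                    continue
                fid = feature_id("response", subset, protein, stim)
                cols[fid] = stim_vals[protein] - base[protein]
                defs_rows.append(
                    dict(feature_id=fid, feature_class="response",
                         cell_type=subset, protein=protein, stimulus=stim)
                )

    values = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    defs = pd.DataFrame(defs_rows).set_index("feature_id")

    # empty-population handling: drop overly sparse features, impute the rest
    missing_frac = values.isna().mean()
    dropped = list(missing_frac.index[missing_frac > max_missing_frac])
    values = values.drop(columns=dropped)
    defs = defs.drop(index=dropped)
    imputed = {}
    n_missing = values.isna().sum()
    for fid in values.columns[n_missing > 0]:
        imputed[fid] = int(n_missing[fid])
        values[fid] = values[fid].fillna(values[fid].median())

    return FeatureMatrix(values=values, defs=defs, dropped=dropped, imputed=imputed)
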