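"""Panel filtering, trace-element log transform, per-split standardization.

Trace-element net intensities span several orders of magnitude between
samples, so they are log-transformed (natural log) to stabilize variance and
damp outliers.  Isotope delta values are left on their native per-mil scale.
Standardization parameters are always estimated on a training split and then
applied frozen to held-out samples and to grid predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ChemistryPanel, SampleTable, TRACE_ELEMENT, DEFAULT_DROP


def select_features(panel: ChemistryPanel, drop) -> ChemistryPanel:
    """Return the panel with the variables in ``drop`` removed.

    The canonical default drop list is ``("Mn", "Br", "Ba")`` — elements
    with a large proportion of missing values in the reference data.
    Order of the retained variables is preserved.
    """
    drop = set(drop)
    unknown = drop - set(panel.names)
    if unknown:
        raise KeyError(f"cannot drop unknown variables: {sorted(unknown)}")
    return panel.subset([n for n in panel.names if n not in drop])


def drop_high_missingness(table: SampleTable, threshold: float = 0.2) -> ChemistryPanel:
    """Panel with variables whose missing fraction exceeds ``threshold`` removed.

    This operationalizes the default {Mn, Br, Ba} exclusion for new panels.
    """
    chem = table.chemistry
    frac = np.mean(np.isnan(chem), axis=0)
    drop = [n for n, f in zip(table.panel.names, frac) if f > threshold]
    return select_features(table.panel, drop)


def log_transform_te(table: SampleTable) -> SampleTable:
    """Natural-log transform of the trace-element columns.

    Isotope-ratio columns are untouched.  Nonpositive trace-element values
    (below-detection artifacts; normalized net intensities should be
    positive) become missing, with a warning naming the columns affected.
    """
    df = table.df.copy()
    flagged = []
    for name, kind in zip(table.panel.names, table.panel.kinds):
        if kind != TRACE_ELEMENT:
            continue
        col = df[name].to_numpy(float)
        bad = np.isfinite(col) & (col <= 0)
        if bad.any():
            flagged.append(name)
            col = col.copy()
            col[bad] = np.nan
        with np.errstate(invalid="ignore"):
            df[name] = np.log(col)
    if flagged:
        warnings.warn(
            f"nonpositive trace-element values set to missing in: {flagged}", stacklevel=2
        )
    return SampleTable(df, table.panel)


@dataclass(frozen=True)
class StandardizationParams:
    """Frozen per-variable location/scale estimated on a training split.

    Standard deviations use the n-1 (sample) convention.
    """

    names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def transform_values(self, values: np.ndarray) -> np.ndarray:
        """Standardize an (n, m) or (m,) chemistry array (panel order)."""
        return (np.asarray(values, float) - self.means) / self.sds

    def inverse_transform_values(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, float) * self.sds + self.means


def fit_standardizer(train: SampleTable) -> StandardizationParams:
    """Estimate per-variable mean and sd on the training table.

    Missing values are ignored.  Requires at least two non-missing values
    per variable; a zero-variance column is an error naming the column.
    """
    chem = train.chemistry
    means = np.empty(train.panel.m)
    sds = np.empty(train.panel.m)
    for j, name in enumerate(train.panel.names):
        col = chem[:, j]
        col = col[np.isfinite(col)]
        if len(col) < 2:
            raise ValueError(f"variable {name!r} has fewer than 2 non-missing values")
        means[j] = col.mean()
        sds[j] = col.std(ddof=1)
        if sds[j] <= 0:
            raise ValueError(f"variable {name!r} has zero variance in the training split")
    return StandardizationParams(tuple(train.panel.names), means, sds)


def apply_standardizer(params: StandardizationParams, table: SampleTable) -> SampleTable:
    """Apply frozen training parameters to any table sharing the panel."""
    if tuple(table.panel.names) != params.names:
        raise ValueError("panel does not match the standardizer's variables")
    df = table.df.copy()
    df[list(params.names)] = params.transform_values(table.chemistry)
    return SampleTable(df, table.panel)


def invert_standardizer(params: StandardizationParams, table: SampleTable) -> SampleTable:
    if tuple(table.panel.names) != params.names:
        raise ValueError("panel does not match the standardizer's variables")
    df = table.df.copy()
    df[list(params.names)] = params.inverse_transform_values(table.chemistry)
    return SampleTable(df, table.panel)
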