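"""Nuisance-effect removal for plotting, and descriptive summaries.

For display the fitted contributions of nuisance coefficients (replicate
bias and the intercept by default) are subtracted from the normalized log2
intensities:

    Y_debiased = Y - X_bias @ beta_bias'

The subtraction is exact, so refitting the model on the debiased matrix
leaves every tested effect unchanged and drives the nuisance coefficients to
zero.  Because intercept and replicate bias depend only on the replicate,
they can also be subtracted from observations outside the fitted design
(the intermediate inhibitor doses), which is how the dose–response profiles
over all five concentrations are debiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ROLE_INTERCEPT, ROLE_REPLICATE, DesignMatrix
from .eb_stats import FitResult, ModeratedStats
from .layout import ExperimentLayout

DEFAULT_BIAS_ROLES = (ROLE_REPLICATE, ROLE_INTERCEPT)


@dataclass
class DebiasedMatrix:
    """Nuisance-corrected log2 intensities (proteins × observations)."""

    values: pd.DataFrame
    removed_roles: tuple[str, ...]


def _bias_row(design: DesignMatrix, key: tuple[str, int], cols: list[int]) -> np.ndarray:
    """Design values of the bias columns for one observation key.

    Keys inside the design use the stored row; keys outside it (e.g. the
    intermediate inhibitor doses) are synthesized, which is only possible
    for replicate-determined roles (intercept, replicate_bias).
    """
    if key in design.row_keys:
        return design.matrix[design.row_keys.index(key), cols]
    rep, _ch = key
    out = np.empty(len(cols))
    for i, j in enumerate(cols):
        role, name = design.roles[j], design.names[j]
        if role == ROLE_INTERCEPT:
            out[i] = 1.0
        elif role == ROLE_REPLICATE:
            out[i] = 1.0 if name == f"replicate[{rep}]" else 0.0
        else:
            raise ValueError(
                f"cannot synthesize design value for role {role!r} outside the fitted design"
            )
    return out


def remove_bias(
    Y: pd.DataFrame,
    fit: FitResult,
    roles: tuple[str, ...] = DEFAULT_BIAS_ROLES,
) -> DebiasedMatrix:
    """Subtract the fitted contribution of the given coefficient roles from
    every observation column of Y."""
    design = fit.design
    for role in roles:
        if role not in design.roles:
            raise ValueError(f"role {role!r} absent from the design")
    cols = design.columns_by_role(*roles)
    if not cols:
        return DebiasedMatrix(values=Y.copy(), removed_roles=tuple(roles))

    xb = np.stack([_bias_row(design, key, cols) for key in Y.columns])  # obs × |cols|
    bias = fit.coefficients[:, cols] @ xb.T                             # proteins × obs
    values = pd.DataFrame(Y.to_numpy(float) - bias, index=Y.index, columns=Y.columns)
    return DebiasedMatrix(values=values, removed_roles=tuple(roles))


def dose_response_profile(
    protein: str,
    debiased: DebiasedMatrix,
    layout: ExperimentLayout,
) -> pd.DataFrame:
    """Replicate-averaged debiased log2 intensity per (label, concentration),
    ordered by concentration within label."""
    if protein not in debiased.values.index:
        raise KeyError(f"unknown protein {protein!r}")
    row = debiased.values.loc[protein]
    cells: dict[tuple[str, float], list[float]] = {}
    for rep, ch in layout.observations():
        key = (rep, ch.index)
        if key in row.index:
            cells.setdefault((ch.label, ch.concentration), []).append(float(row[key]))
    records = [
        {"label": lab, "concentration": conc, "mean_log2": float(np.mean(v)), "n_replicates": len(v)}
        for (lab, conc), v in cells.items()
    ]
    out = pd.DataFrame.from_records(records)
    return out.sort_values(["label", "concentration"]).reset_index(drop=True)


def inhibitor_responses(
    debiased: DebiasedMatrix,
    layout: ExperimentLayout,
    dose: float = 25.0,
) -> pd.DataFrame:
    """Per-protein mean log2 response to each inhibitor at the given dose:
    mean debiased intensity at ``dose`` minus mean at 0 µM (the control
    channels are shared between inhibitors)."""
    labels = sorted({ch.label for _r, ch in layout.observations() if ch.concentration > 0})
    zero_keys = [
        (rep, ch.index) for rep, ch in layout.observations() if ch.concentration == 0
    ]
    base = debiased.values[zero_keys].mean(axis=1)
    out = {}
    for lab in labels:
        keys = [
            (rep, ch.index)
            for rep, ch in layout.observations()
            if ch.label == lab and ch.concentration == dose
        ]
        if not keys:
            raise ValueError(f"no channel with label {lab!r} at {dose} in layout")
        out[lab] = debiased.values[keys].mean(axis=1) - base
    return pd.DataFrame(out, index=debiased.values.index)


def export_volcano(
    stats: ModeratedStats,
    gene_names: pd.Series | None = None,
    known_targets: pd.Series | None = None,
    ceiling: float = 16.0,
) -> pd.DataFrame:
    """Plot-ready volcano records: effect on x, -log10 adjusted p on y
    (capped at ``ceiling`` for p = 0), with significance and known-target
    annotations."""
    with np.errstate(divide="ignore"):
        y = -np.log10(stats.p_adjusted)
    capped = ~np.isfinite(y) | (y > ceiling)
    y = np.where(capped, ceiling, y)
    out = pd.DataFrame(
        {
            "effect": stats.effect,
            "neg_log10_p_adjusted": y,
            "capped": capped,
            "significant": stats.significant,
        },
        index=pd.Index(stats.protein_ids, name="protein"),
    )
    if gene_names is not None:
        out.insert(0, "gene_name", gene_names.reindex(out.index))
    if known_targets is not None:
        out["known_target"] = known_targets.reindex(out.index).fillna(False).astype(bool)
    return out
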