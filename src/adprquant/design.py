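"""Design matrices for the two multiplexed linear models.

Cofactor-preference model (TMT6plex, per protein g and observation i):

    log2pm_gi ~ intercept + cofactor_i * delta_g
                + ln(conc_i) * gamma_g + replicate-bias dummies

with ``cofactor`` sum-coded +1 for 2YnAd and -1 for 6YnAd, so a positive
coefficient means 2YnAd preference; concentration enters as the natural log
of the feeding concentration in mM (the log base only rescales the
coefficient, never its t-statistic).

Inhibitor-response model (TMT10plex, fitted only on the 0 µM and 25 µM
channels to avoid overfitting the intermediate doses):

    log2pm_gi ~ intercept + preference_i * pi_g + inhibited_i * eta_g
                + replicate-bias dummies

with ``preference`` coded -1 for Olaparib, +1 for Rucaparib and 0 for the
no-inhibitor channels (positive coefficient = higher intensity under
Rucaparib), and ``inhibited`` 1 whenever any inhibitor is present.

Replicate bias uses 0/1 dummies with the first replicate absorbed into the
intercept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .layout import COFACTOR, INHIBITOR, ExperimentLayout

ROLE_INTERCEPT = "intercept"
ROLE_COFACTOR = "cofactor_effect"
ROLE_LOGCONC = "log_concentration_effect"
ROLE_PREFERENCE = "inhibitor_preference"
ROLE_INHIBITION = "inhibition_effect"
ROLE_REPLICATE = "replicate_bias"


class DesignError(ValueError):
    pass


@dataclass
class DesignMatrix:
    """Observations × coefficients matrix with named coefficient roles."""

    matrix: np.ndarray
    row_keys: list[tuple[str, int]]      # (replicate, channel_index) per row
    names: list[str]
    roles: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (len(self.row_keys), len(self.names)):
            raise DesignError("design matrix shape does not match row/column labels")
        if len(self.names) != len(self.roles):
            raise DesignError("one role per coefficient required")

    @property
    def n_observations(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_coefficients(self) -> int:
        return self.matrix.shape[1]

    def column_index(self, name_or_role: str) -> int:
        """Resolve a coefficient by name, or by role when unambiguous."""
        if name_or_role in self.names:
            return self.names.index(name_or_role)
        hits = [j for j, r in enumerate(self.roles) if r == name_or_role]
        if len(hits) == 1:
            return hits[0]
        if len(hits) > 1:
            raise DesignError(
                f"role {name_or_role!r} matches several columns; use a column name"
            )
        raise DesignError(f"no coefficient named {name_or_role!r}")

    def columns_by_role(self, *roles: str) -> list[int]:
        return [j for j, r in enumerate(self.roles) if r in roles]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.row_keys, names=["replicate", "channel"])
        return pd.DataFrame(self.matrix, index=idx, columns=self.names)


def _replicate_dummies(
    layout: ExperimentLayout,
    keys: list[tuple[str, int]],
    absorb_first: bool,
) -> tuple[np.ndarray, list[str]]:
    reps = layout.replicates[1:] if absorb_first else layout.replicates
    cols = np.zeros((len(keys), len(reps)))
    for i, (rep, _ch) in enumerate(keys):
        for j, r in enumerate(reps):
            if rep == r:
                cols[i, j] = 1.0
    return cols, [f"replicate[{r}]" for r in reps]


def cofactor_design(
    layout: ExperimentLayout,
    absorb_first_replicate: bool = True,
) -> DesignMatrix:
    """Design for the 2YnAd/6YnAd cofactor-preference model."""
    if layout.kind != COFACTOR:
        raise DesignError("cofactor_design requires a cofactor layout")
    keys = []
    rows = []
    for rep, ch in layout.observations():
        if ch.concentration <= 0:
            raise DesignError(
                f"channel {ch.index}: concentration must be > 0 mM (log undefined)"
            )
        if ch.label == "2YnAd":
            cof = 1.0
        elif ch.label == "6YnAd":
            cof = -1.0
        else:  # pragma: no cover - layout already validates labels
            raise DesignError(f"unknown cofactor label {ch.label!r}")
        keys.append((rep, ch.index))
        rows.append([1.0, cof, math.log(ch.concentration)])
    base = np.asarray(rows)
    dummies, dummy_names = _replicate_dummies(layout, keys, absorb_first_replicate)
    return DesignMatrix(
        matrix=np.hstack([base, dummies]),
        row_keys=keys,
        names=["intercept", "cofactor", "log_concentration", *dummy_names],
        roles=[ROLE_INTERCEPT, ROLE_COFACTOR, ROLE_LOGCONC]
        + [ROLE_REPLICATE] * dummies.shape[1],
    )


def inhibitor_design(
    layout: ExperimentLayout,
    included_concentrations: tuple[float, ...] = (0.0, 25.0),
    absorb_first_replicate: bool = True,
) -> DesignMatrix:
    """Design for the Olaparib/Rucaparib model, restricted to the stated
    concentrations (the control and top dose by default)."""
    if layout.kind != INHIBITOR:
        raise DesignError("inhibitor_design requires an inhibitor layout")
    included = set(float(c) for c in included_concentrations)
    keys = []
    rows = []
    for rep, ch in layout.observations():
        if float(ch.concentration) not in included:
            continue
        if ch.concentration == 0 or ch.label == "none":
            pref, inhibited = 0.0, 0.0
        elif ch.label == "Olaparib":
            pref, inhibited = -1.0, 1.0
        elif ch.label == "Rucaparib":
            pref, inhibited = 1.0, 1.0
        else:  # pragma: no cover
            raise DesignError(f"unknown inhibitor label {ch.label!r}")
        keys.append((rep, ch.index))
        rows.append([1.0, pref, inhibited])
    if not any(r[2] == 0.0 for r in rows):
        raise DesignError(
            "no zero-concentration channel selected: inhibition effect is "
            "unidentifiable without the control"
        )
    base = np.asarray(rows)
    dummies, dummy_names = _replicate_dummies(layout, keys, absorb_first_replicate)
    return DesignMatrix(
        matrix=np.hstack([base, dummies]),
        row_keys=keys,
        names=["intercept", "preference", "inhibited", *dummy_names],
        roles=[ROLE_INTERCEPT, ROLE_PREFERENCE, ROLE_INHIBITION]
        + [ROLE_REPLICATE] * dummies.shape[1],
    )


@dataclass
class DesignDiagnostics:
    rank: int
    condition_number: float
    aliased: list[tuple[str, list[str]]] = field(default_factory=list)

    @property
    def full_rank(self) -> bool:
        return not self.aliased


def validate_design(design: DesignMatrix, raise_on_deficient: bool = True) -> DesignDiagnostics:
    """Report rank, condition number and aliased (linearly dependent)
    columns; raise on rank deficiency unless told otherwise."""
    x = design.matrix
    rank = int(np.linalg.matrix_rank(x))
    sv = np.linalg.svd(x, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")

    aliased: list[tuple[str, list[str]]] = []
    if rank < design.n_coefficients:
        # Greedy scan: a column is aliased if it lies in the span of the
        # independent columns accepted before it.
        independent: list[int] = []
        for j in range(design.n_coefficients):
            if not independent:
                independent.append(j)
                continue
            basis = x[:, independent]
            coef, *_ = linalg.lstsq(basis, x[:, j])
            resid = x[:, j] - basis @ coef
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(x[:, j])):
                partners = [design.names[independent[k]] for k in np.flatnonzero(np.abs(coef) > 1e-8)]
                aliased.append((design.names[j], partners))
            else:
                independent.append(j)
    diag = DesignDiagnostics(rank=rank, condition_number=cond, aliased=aliased)
    if raise_on_deficient and aliased:
        deps = "; ".join(f"{name} ~ {' + '.join(p)}" for name, p in aliased)
        raise DesignError(f"rank-deficient design (rank {rank}): {deps}")
    return diag
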