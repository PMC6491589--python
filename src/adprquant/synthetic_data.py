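"""Synthetic MaxQuant-style proteinGroups tables with known ground truth.

The generator emulates the statistical structure the analysis assumes, so
parameter recovery is a sharp test rather than a robustness study:

* protein log2 abundances are Gaussian around a log-normal baseline;
* condition effects enter additively on the log2 scale exactly as the
  corresponding design matrix encodes them (sum-coded cofactor preference
  plus a log-concentration slope for the TMT6plex experiment; inhibitor
  preference and inhibition for the TMT10plex experiment, ramped across the
  intermediate doses by a saturating log curve that reaches 1 at the top
  dose);
* per-protein error variances are drawn from a scaled-inverse-chi-square
  prior (optionally with an intensity trend), the same family the
  empirical-Bayes step estimates;
* each replicate beyond the first carries a constant log2 offset
  (technical replicate bias);
* intensities are exponentiated (base 2) and columns rescaled so the clean
  proteins sum to the configured library sizes;
* decoy rows — contaminants, reverse hits, site-only identifications,
  single-peptide proteins and rows with one injected zero intensity — are
  appended and flagged with MaxQuant's "+" marker conventions.

It does not simulate reporter-ion ratio compression, isotope-impurity
cross-talk, or peptide-to-protein rollup.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .design import ROLE_COFACTOR, ROLE_INHIBITION, ROLE_LOGCONC, ROLE_PREFERENCE
from .io_maxquant import ColumnDialect
from .layout import COFACTOR, ExperimentLayout


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Effects are log2 units.  ``n_proteins`` counts clean (analysable)
    proteins; decoys are added on top.  ``variance_prior`` is the
    (d0, s0^2) of the scaled-inverse-chi-square error-variance prior;
    ``trend_spec``, when given, maps baseline log2 abundance to s0^2 and
    overrides the constant scale.
    """

    layout: ExperimentLayout
    n_proteins: int = 5000
    fraction_responsive: float = 0.10
    effect_size_mean: float = 1.0
    effect_size_sd: float = 0.25
    concentration_slope_mean: float = 0.3   # log2 per ln(mM), cofactor runs
    concentration_slope_sd: float = 0.1
    inhibition_effect_mean: float = -1.0    # log2 drop under inhibition
    inhibition_effect_sd: float = 0.25
    replicate_offsets: tuple[float, ...] | None = None  # default: 0, then +0.3 each
    variance_prior: tuple[float, float] = (4.0, 0.05)
    trend_spec: Callable[[np.ndarray], np.ndarray] | None = None
    baseline_mean: float = 7.5
    baseline_sd: float = 2.0
    n_contaminants: int = 20
    n_reverse: int = 10
    n_only_by_site: int = 10
    n_low_peptide: int = 15
    n_with_zeros: int = 10
    library_size_range: tuple[float, float] = (5e8, 1.5e9)
    dose_ramp_scale: float = 1.0            # µM; half-saturation of the dose ramp
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_responsive <= 1:
            raise ValueError("fraction_responsive must be in [0, 1]")
        d0, s0 = self.variance_prior
        if d0 <= 0 or s0 < 0:
            raise ValueError("variance prior needs d0 > 0 and s0^2 >= 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library sizes must be positive with lo <= hi")
        if self.replicate_offsets is not None and len(self.replicate_offsets) != len(
            self.layout.replicates
        ):
            raise ValueError("one replicate offset per layout replicate required")


@dataclass
class SyntheticTruth:
    """Ground truth paired with a generated table: per-protein coefficients
    by role, error variances, responsive flags and decoy labels."""

    table: pd.DataFrame            # indexed by protein id
    replicate_offsets: tuple[float, ...]
    library_sizes: np.ndarray      # clean-row column totals, layout order
    seed: int

    def clean(self) -> pd.DataFrame:
        return self.table[self.table["decoy_class"] == "clean"]


def _offsets(config: SimulationConfig) -> np.ndarray:
    if config.replicate_offsets is not None:
        return np.asarray(config.replicate_offsets, float)
    return 0.3 * np.arange(len(config.layout.replicates))


def _dose_ramp(conc: float, top: float, scale: float) -> float:
    # Saturating log ramp: 0 at 0, exactly 1 at the top dose.
    if conc <= 0:
        return 0.0
    return float(np.log1p(conc / scale) / np.log1p(top / scale))


def _clean_log2_means(config: SimulationConfig, rng: np.random.Generator):
    """Per-protein, per-observation log2 means plus the truth columns."""
    layout = config.layout
    n = config.n_proteins
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    responsive = np.zeros(n, dtype=bool)
    n_resp = int(round(config.fraction_responsive * n))
    if n_resp:
        responsive[rng.choice(n, size=n_resp, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=n)
    magnitude = np.abs(rng.normal(config.effect_size_mean, config.effect_size_sd, size=n))
    primary = np.where(responsive, signs * magnitude, 0.0)

    offsets = _offsets(config)
    obs = list(layout.observations())
    rep_index = {r: i for i, r in enumerate(layout.replicates)}

    truth = {"intercept": mu, "responsive": responsive}
    means = np.tile(mu[:, None], (1, len(obs)))
    for i, (rep, ch) in enumerate(obs):
        means[:, i] += offsets[rep_index[rep]]

    if layout.kind == COFACTOR:
        slope = rng.normal(
            config.concentration_slope_mean, config.concentration_slope_sd, size=n
        )
        for i, (_rep, ch) in enumerate(obs):
            cof = 1.0 if ch.label == "2YnAd" else -1.0
            means[:, i] += cof * primary + slope * np.log(ch.concentration)
        truth[ROLE_COFACTOR] = primary
        truth[ROLE_LOGCONC] = slope
    else:
        inhibition = np.where(
            responsive,
            rng.normal(config.inhibition_effect_mean, config.inhibition_effect_sd, size=n),
            0.0,
        )
        top = max(ch.concentration for _r, ch in obs)
        for i, (_rep, ch) in enumerate(obs):
            ramp = _dose_ramp(ch.concentration, top, config.dose_ramp_scale)
            pref = {"Olaparib": -1.0, "Rucaparib": 1.0}.get(ch.label, 0.0)
            means[:, i] += ramp * (pref * primary + inhibition)
        truth[ROLE_PREFERENCE] = primary
        truth[ROLE_INHIBITION] = inhibition
    return means, truth


def _draw_variances(config: SimulationConfig, mu: np.ndarray, rng: np.random.Generator):
    d0, s0_sq = config.variance_prior
    scale = config.trend_spec(mu) if config.trend_spec is not None else np.full(mu.size, s0_sq)
    return scale * d0 / rng.chisquare(d0, size=mu.size)


def generate_experiment(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a proteinGroups-style table and its ground truth.

    Fully reproducible from ``config.seed``: the same config yields a
    byte-identical table.
    """
    rng = np.random.default_rng(config.seed)
    layout = config.layout
    obs = list(layout.observations())
    n_obs = len(obs)
    dialect = ColumnDialect()
    n_rep = len(layout.replicates)

    means, truth_cols = _clean_log2_means(config, rng)
    sigma2 = _draw_variances(config, truth_cols["intercept"], rng)
    noise = np.sqrt(sigma2)[:, None] * rng.standard_normal((config.n_proteins, n_obs))
    clean = 2.0 ** (means + noise)

    lib_lo, lib_hi = config.library_size_range
    target_sizes = rng.uniform(lib_lo, lib_hi, size=n_obs)
    col_scale = target_sizes / clean.sum(axis=0)
    clean *= col_scale

    # --- decoy rows -----------------------------------------------------
    decoy_classes = (
        ["contaminant"] * config.n_contaminants
        + ["reverse"] * config.n_reverse
        + ["only_by_site"] * config.n_only_by_site
        + ["low_peptide"] * config.n_low_peptide
        + ["zero_injected"] * config.n_with_zeros
    )
    n_decoy = len(decoy_classes)
    decoy_mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_decoy)
    decoy = 2.0 ** (decoy_mu[:, None] + 0.3 * rng.standard_normal((n_decoy, n_obs)))
    decoy *= col_scale  # same scale as clean rows so magnitudes are comparable
    zero_rows = [i for i, c in enumerate(decoy_classes) if c == "zero_injected"]
    for i in zero_rows:
        decoy[i, rng.integers(n_obs)] = 0.0

    # --- identifiers, flags, peptide counts -----------------------------
    prefix = {"contaminant": "CON__SYNC", "reverse": "REV__SYNR", "only_by_site": "SYNS",
              "low_peptide": "SYNL", "zero_injected": "SYNZ"}
    ids = [f"SYNP{i:05d}" for i in range(config.n_proteins)]
    genes = [f"GENE{i}" for i in range(config.n_proteins)]
    counters: dict[str, int] = {}
    for c in decoy_classes:
        k = counters.get(c, 0)
        counters[c] = k + 1
        ids.append(f"{prefix[c]}{k:04d}")
        genes.append("")
    peptides = np.concatenate(
        [
            rng.integers(2, 41, size=config.n_proteins),
            np.array([1 if c == "low_peptide" else int(rng.integers(2, 41)) for c in decoy_classes], int),
        ]
    )

    intensities = np.vstack([clean, decoy]) if n_decoy else clean
    flag = lambda cls: ["+" if c == cls else "" for c in [""] * config.n_proteins + decoy_classes]

    table = pd.DataFrame({"Protein IDs": ids, "Gene names": genes, "Peptides": peptides})
    for i, (rep, ch) in enumerate(obs):
        col = dialect.intensity_column(rep, ch.index, n_rep)
        table[col] = intensities[:, i]
    table["Only identified by site"] = flag("only_by_site")
    table["Reverse"] = flag("reverse")
    table["Potential contaminant"] = flag("contaminant")

    truth_table = pd.DataFrame(
        {
            "decoy_class": [""] * config.n_proteins + decoy_classes,
            "responsive": np.concatenate([truth_cols["responsive"], np.zeros(n_decoy, bool)]),
            "sigma2": np.concatenate([sigma2, np.zeros(n_decoy)]),
        },
        index=pd.Index(ids, name="protein"),
    )
    truth_table.loc[truth_table["decoy_class"] == "", "decoy_class"] = "clean"
    for key in ("intercept", ROLE_COFACTOR, ROLE_LOGCONC, ROLE_PREFERENCE, ROLE_INHIBITION):
        if key in truth_cols:
            truth_table[key] = np.concatenate([truth_cols[key], np.zeros(n_decoy)])
    # decoys carry no true effects by construction
    truth_table.loc[truth_table["decoy_class"] != "clean", "responsive"] = False

    # shuffle rows so decoys are interleaved as in real output
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    truth_table = truth_table.iloc[order]

    truth = SyntheticTruth(
        table=truth_table,
        replicate_offsets=tuple(_offsets(config)),
        library_sizes=target_sizes,
        seed=config.seed,
    )
    return table, truth


def generate_null_experiment(config: SimulationConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """As :func:`generate_experiment` but with every condition effect forced
    to zero (responsive fraction, concentration slope and inhibition all 0);
    replicate bias and the intercept remain."""
    null_config = dataclasses.replace(
        config,
        fraction_responsive=0.0,
        concentration_slope_mean=0.0,
        concentration_slope_sd=0.0,
        inhibition_effect_mean=0.0,
        inhibition_effect_sd=0.0,
    )
    return generate_experiment(null_config)


def write_protein_groups(table: pd.DataFrame, path) -> None:
    """Write a generated table as a MaxQuant-style proteinGroups TSV."""
    table.to_csv(path, sep="\t", index=False)


def write_truth(truth: SyntheticTruth, path) -> None:
    truth.table.to_csv(path, sep="\t")
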