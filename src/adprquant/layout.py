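"""Experiment layouts for multiplexed TMT designs.

A layout declares, for every reporter channel of every technical replicate,
which experimental condition that channel carries.  Two experiment kinds are
supported:

* ``cofactor`` — a TMT6plex comparing metabolic labelling by the two
  clickable NAD+ precursors 2YnAd and 6YnAd at several feeding
  concentrations (mM).
* ``inhibitor`` — a TMT10plex dose series of the PARP inhibitors Olaparib
  and Rucaparib (µM), with the 0 µM channels serving as the DMSO control.

The layout is the single source of truth for observation ordering: every
reporter matrix and design matrix in this package orders its observations
replicate-major, channel-minor, exactly as :meth:`ExperimentLayout.observations`
yields them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

COFACTOR = "cofactor"
INHIBITOR = "inhibitor"

COFACTOR_LABELS = ("2YnAd", "6YnAd")
INHIBITOR_LABELS = ("Olaparib", "Rucaparib", "none")


@dataclass(frozen=True)
class Channel:
    """One reporter channel: its index within the plex and its condition."""

    index: int
    label: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(
                f"channel {self.index}: concentration must be non-negative, "
                f"got {self.concentration}"
            )


@dataclass(frozen=True)
class ExperimentLayout:
    """Channel-to-condition mapping for one multiplexed experiment.

    Parameters
    ----------
    kind:
        ``"cofactor"`` or ``"inhibitor"``.
    replicates:
        Ordered technical-replicate identifiers.  Each replicate is one
        TMT plex (one set of reporter columns in proteinGroups.txt).
    channels:
        Ordered channel descriptors, shared by all replicates.
    """

    kind: str
    replicates: tuple[str, ...]
    channels: tuple[Channel, ...]

    def __post_init__(self) -> None:
        if self.kind not in (COFACTOR, INHIBITOR):
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        if not self.replicates:
            raise ValueError("layout needs at least one replicate")
        if len(set(self.replicates)) != len(self.replicates):
            raise ValueError("replicate ids must be unique")
        if not self.channels:
            raise ValueError("layout needs at least one channel")
        idx = [c.index for c in self.channels]
        if len(set(idx)) != len(idx):
            raise ValueError("channel indices must be unique")
        desc = [(c.label, c.concentration) for c in self.channels]
        if len(set(desc)) != len(desc):
            raise ValueError("channel (label, concentration) descriptors must be unique")
        allowed = COFACTOR_LABELS if self.kind == COFACTOR else INHIBITOR_LABELS
        for c in self.channels:
            if c.label not in allowed:
                raise ValueError(
                    f"channel {c.index}: label {c.label!r} invalid for "
                    f"{self.kind} experiment (allowed: {allowed})"
                )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_observations(self) -> int:
        return len(self.replicates) * len(self.channels)

    def observations(self) -> Iterator[tuple[str, Channel]]:
        """Yield (replicate, channel) pairs, replicate-major."""
        for rep in self.replicates:
            for ch in self.channels:
                yield rep, ch

    def observation_keys(self) -> list[tuple[str, int]]:
        """(replicate_id, channel_index) keys in canonical order."""
        return [(rep, ch.index) for rep, ch in self.observations()]

    # ------------------------------------------------------------------
    # canonical study layouts
    # ------------------------------------------------------------------

    @classmethod
    def tmt6_cofactor(
        cls,
        replicates: tuple[str, ...] = ("R1", "R2"),
        concentrations_mm: tuple[float, ...] = (1.0, 0.5, 0.25),
    ) -> "ExperimentLayout":
        """TMT6plex cofactor-preference layout: 2YnAd then 6YnAd, each at
        the given feeding concentrations (mM, descending)."""
        channels = []
        i = 0
        for label in COFACTOR_LABELS:
            for conc in concentrations_mm:
                channels.append(Channel(i, label, conc))
                i += 1
        return cls(COFACTOR, tuple(replicates), tuple(channels))

    @classmethod
    def tmt10_inhibitor(
        cls,
        replicates: tuple[str, ...] = ("R1", "R2"),
        concentrations_um: tuple[float, ...] = (25.0, 5.0, 1.0, 0.2, 0.0),
    ) -> "ExperimentLayout":
        """TMT10plex inhibitor layout: Olaparib 25…0 µM (reporters 0–4)
        then Rucaparib 25…0 µM (reporters 5–9)."""
        channels = []
        i = 0
        for label in ("Olaparib", "Rucaparib"):
            for conc in concentrations_um:
                channels.append(Channel(i, label, conc))
                i += 1
        return cls(INHIBITOR, tuple(replicates), tuple(channels))

    # ------------------------------------------------------------------
    # config (de)serialisation
    # ------------------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "replicates": list(self.replicates),
            "channels": [
                {"index": c.index, "label": c.label, "concentration": c.concentration}
                for c in self.channels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentLayout":
        return cls(
            kind=d["kind"],
            replicates=tuple(d["replicates"]),
            channels=tuple(
                Channel(int(c["index"]), str(c["label"]), float(c["concentration"]))
                for c in d["channels"]
            ),
        )
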