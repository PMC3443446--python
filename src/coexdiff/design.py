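"""Experimental design: dose x time x replicate sample layouts.

The reference design is a 3 dose (0, 10, 100 cGy) x 4 time (0, 3, 8, 24 h)
x 2 replicate layout — 24 samples total — but any fully crossed layout is
supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class StudyDesign:
    """A fully crossed dose x time x replicate design.

    Samples are ordered dose-major, then time, then replicate; ``sample_ids``
    holds one label per sample in that order.
    """

    doses: tuple[float, ...]
    times: tuple[float, ...]
    replicates: int
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if len(self.doses) == 0 or len(self.times) == 0:
            raise ValueError("doses and times must be non-empty")
        if len(set(self.doses)) != len(self.doses):
            raise ValueError(f"duplicate dose levels: {self.doses}")
        if len(set(self.times)) != len(self.times):
            raise ValueError(f"duplicate time levels: {self.times}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.sample_ids:
            ids = tuple(
                f"d{_fmt(d)}_t{_fmt(t)}_r{r}"
                for d in self.doses
                for t in self.times
                for r in range(1, self.replicates + 1)
            )
            object.__setattr__(self, "sample_ids", ids)
        if len(self.sample_ids) != self.n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.n_samples} samples"
            )

    @property
    def n_samples(self) -> int:
        return len(self.doses) * len(self.times) * self.replicates

    @property
    def n_cells(self) -> int:
        return len(self.doses) * len(self.times)

    def conditions(self) -> list[tuple[float, float, int]]:
        """(dose, time, replicate) triple for every sample, in sample order."""
        return [
            (d, t, r)
            for d in self.doses
            for t in self.times
            for r in range(1, self.replicates + 1)
        ]

    def sample_table(self) -> pd.DataFrame:
        """Sample sheet: sample_id, dose_cGy, time_h, replicate."""
        rows = self.conditions()
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "dose_cGy": [d for d, _, _ in rows],
                "time_h": [t for _, t, _ in rows],
                "replicate": [r for _, _, r in rows],
            }
        )

    def column_indices(self, doses=None, times=None) -> list[int]:
        """Positional indices of samples matching the given dose/time levels."""
        doses = set(self.doses if doses is None else doses)
        times = set(self.times if times is None else times)
        return [
            i
            for i, (d, t, _) in enumerate(self.conditions())
            if d in doses and t in times
        ]

    def cell_indices(self) -> dict[tuple[float, float], list[int]]:
        """Map (dose, time) -> positional sample indices of that cell."""
        cells: dict[tuple[float, float], list[int]] = {}
        for i, (d, t, _) in enumerate(self.conditions()):
            cells.setdefault((d, t), []).append(i)
        return cells


def _fmt(x: float) -> str:
    return f"{x:g}".replace(".", "p").replace("-", "m")


def generate_design(
    doses, times, replicates: int, seed: int | None = None
) -> StudyDesign:
    """Build a fully crossed design.

    ``seed`` is accepted for interface symmetry with the stochastic
    generators; the layout itself is deterministic.
    """
    return StudyDesign(tuple(doses), tuple(times), int(replicates))


def read_sample_sheet(path) -> StudyDesign:
    """Reconstruct a StudyDesign from a tab-delimited sample sheet."""
    df = pd.read_csv(path, sep="\t")
    doses = tuple(dict.fromkeys(df["dose_cGy"]))
    times = tuple(dict.fromkeys(df["time_h"]))
    reps = int(df["replicate"].max())
    return StudyDesign(doses, times, reps, tuple(df["sample_id"].astype(str)))
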