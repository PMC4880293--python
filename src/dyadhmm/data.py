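"""Count tables and observation datasets for hairpin BS/oxBS experiments.

The on-disk format is a tab-separated table with header

    locus  position  day  treatment  count_TT  count_TC  count_CT  count_CC

where ``position`` is a CpG position label or ``aggregate`` for counts summed
across the positions of a locus, ``day`` is the observation day (0 = the
serum/LIF baseline before the shift to 2i medium) and ``treatment`` is
``bs`` or ``ox``.  Conversion profiles travel in a companion table with
columns ``locus  day  treatment  c  d  e_or_f``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .emission import OBS_STATES, TREATMENTS, ConversionProfile

COUNT_COLUMNS = [f"count_{s}" for s in OBS_STATES]
TABLE_COLUMNS = ["locus", "position", "day", "treatment", *COUNT_COLUMNS]
PROFILE_COLUMNS = ["locus", "day", "treatment", "c", "d", "e_or_f"]

AGGREGATE = "aggregate"


class CountTableError(ValueError):
    """Raised for malformed count or conversion-profile tables."""


@dataclass
class ObservationDataset:
    """Dyad-pattern counts of one locus (or one CpG position) over time.

    ``counts`` maps ``(day, treatment)`` to an integer 4-vector over the
    observable states TT/TC/CT/CC; ``profiles`` maps the same keys to the
    conversion profile in force for that measurement.  ``divisions_per_day``
    converts observation days into division counts (default one division per
    24 h, the culture condition the model was designed for).
    """

    locus: str
    counts: dict[tuple[int, str], np.ndarray]
    profiles: dict[tuple[int, str], ConversionProfile]
    position: str = AGGREGATE
    divisions_per_day: int = 1

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            n = np.asarray(n)
            if n.shape != (4,) or np.any(n < 0) or not np.issubdtype(n.dtype, np.integer):
                raise CountTableError(f"counts for {key} must be a nonnegative integer 4-vector")
            self.counts[key] = n.astype(np.int64)
            if key not in self.profiles:
                raise CountTableError(f"no conversion profile for {key}")

    @property
    def days(self) -> list[int]:
        return sorted({day for day, _ in self.counts})

    @property
    def post_days(self) -> list[int]:
        return [d for d in self.days if d > 0]

    def has_day0(self) -> bool:
        return (0, "bs") in self.counts and (0, "ox") in self.counts

    def divisions(self, day: int) -> int:
        return int(day) * self.divisions_per_day

    def subset(self, days: list[int]) -> "ObservationDataset":
        """Dataset restricted to the given observation days."""
        keep = set(days)
        return ObservationDataset(
            locus=self.locus,
            counts={k: v.copy() for k, v in self.counts.items() if k[0] in keep},
            profiles={k: v for k, v in self.profiles.items() if k[0] in keep},
            position=self.position,
            divisions_per_day=self.divisions_per_day,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (day, treatment), n in sorted(self.counts.items()):
            rows.append([self.locus, self.position, day, treatment, *n.tolist()])
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)

    def profiles_frame(self) -> pd.DataFrame:
        rows = []
        for (day, treatment), prof in sorted(self.profiles.items()):
            rows.append([self.locus, day, treatment, prof.c, prof.d, prof.e_or_f])
        return pd.DataFrame(rows, columns=PROFILE_COLUMNS).drop_duplicates()


def aggregate_positions(datasets: list[ObservationDataset]) -> ObservationDataset:
    """Sum counts across the CpG positions of one locus (shared profiles)."""
    if not datasets:
        raise ValueError("no datasets to aggregate")
    first = datasets[0]
    counts: dict[tuple[int, str], np.ndarray] = {}
    for ds in datasets:
        if ds.locus != first.locus:
            raise ValueError("cannot aggregate across different loci")
        for key, n in ds.counts.items():
            counts[key] = counts.get(key, np.zeros(4, dtype=np.int64)) + n
    return ObservationDataset(
        locus=first.locus,
        counts=counts,
        profiles=dict(first.profiles),
        position=AGGREGATE,
        divisions_per_day=first.divisions_per_day,
    )


def _parse_counts_frame(df: pd.DataFrame, path: str) -> pd.DataFrame:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: missing columns {missing}")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["treatment"] not in TREATMENTS:
            raise CountTableError(f"{path}:{line}: unknown treatment {row['treatment']!r}")
        for col in COUNT_COLUMNS:
            v = row[col]
            if not float(v).is_integer() or v < 0:
                raise CountTableError(f"{path}:{line}: {col}={v!r} is not a nonnegative integer")
    dup = df.duplicated(subset=["locus", "position", "day", "treatment"], keep=False)
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise CountTableError(f"{path}:{line}: duplicate (locus, position, day, treatment) key")
    return df


def read_profiles(path) -> dict[tuple[str, int, str], ConversionProfile]:
    """Read a conversion-profile table keyed by (locus, day, treatment).

    A row with locus ``*`` (or day -1) acts as a global fallback for its
    treatment.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: missing columns {missing}")
    profiles: dict[tuple[str, int, str], ConversionProfile] = {}
    for _, row in df.iterrows():
        t = row["treatment"]
        if t not in TREATMENTS:
            raise CountTableError(f"{path}: unknown treatment {t!r}")
        kwargs = dict(c=row["c"], d=row["d"], day=int(row["day"]), locus=str(row["locus"]))
        kwargs["e" if t == "bs" else "f"] = row["e_or_f"]
        profiles[(str(row["locus"]), int(row["day"]), t)] = ConversionProfile(t, **kwargs)
    return profiles


def write_profiles(profiles: dict, path) -> None:
    rows = [
        [locus, day, treatment, p.c, p.d, p.e_or_f]
        for (locus, day, treatment), p in sorted(profiles.items())
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def _lookup_profile(profiles: dict, locus: str, day: int, treatment: str) -> ConversionProfile:
    for key in ((locus, day, treatment), ("*", day, treatment), ("*", -1, treatment)):
        if key in profiles:
            return profiles[key]
    raise CountTableError(f"no conversion profile for locus={locus!r} day={day} treatment={treatment}")


def read_counts(
    counts_path,
    profiles_path=None,
    profiles: dict | None = None,
    divisions_per_day: int = 1,
) -> dict[tuple[str, str], ObservationDataset]:
    """Read a count table into one ObservationDataset per (locus, position).

    Conversion profiles come either from ``profiles_path``/``profiles`` or
    default to error-free conversion when neither is given.
    """
    df = _parse_counts_frame(pd.read_csv(counts_path, sep="\t"), str(counts_path))
    if profiles is None:
        profiles = read_profiles(profiles_path) if profiles_path is not None else {}

    datasets: dict[tuple[str, str], ObservationDataset] = {}
    for (locus, position), grp in df.groupby(["locus", "position"], sort=True):
        counts: dict[tuple[int, str], np.ndarray] = {}
        profs: dict[tuple[int, str], ConversionProfile] = {}
        for _, row in grp.iterrows():
            day, treatment = int(row["day"]), row["treatment"]
            counts[(day, treatment)] = row[COUNT_COLUMNS].to_numpy(dtype=np.int64)
            if profiles:
                profs[(day, treatment)] = _lookup_profile(profiles, str(locus), day, treatment)
            else:
                from .emission import perfect_profile

                profs[(day, treatment)] = perfect_profile(treatment, day=day)
        datasets[(str(locus), str(position))] = ObservationDataset(
            locus=str(locus),
            counts=counts,
            profiles=profs,
            position=str(position),
            divisions_per_day=divisions_per_day,
        )
    return datasets


def write_counts(datasets, path) -> None:
    """Write one or several ObservationDatasets to a TSV count table."""
    if isinstance(datasets, ObservationDataset):
        datasets = [datasets]
    elif isinstance(datasets, dict):
        datasets = list(datasets.values())
    pd.concat([ds.to_frame() for ds in datasets], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
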