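"""Datasets, fixtures, and file I/O.

Ships the guinea-pig survival-time fixtures used throughout the tests and
documentation: the complete 72-observation sample, the 36 group-minimum
(first-failure, k=2) values, and the three progressively censored
subsamples with their schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sampling import CensoringScheme, parse_scheme

__all__ = ["Dataset", "DatasetError", "load_dataset", "first_failure_grouping", "FIXTURES"]


class DatasetError(ValueError):
    """Raised when a dataset file or fixture cannot be loaded."""


@dataclass(frozen=True)
class Dataset:
    """Positive failure times, a label, and an optional censoring scheme.

    An absent scheme means complete (uncensored) data.
    """

    times: np.ndarray
    label: str = ""
    censoring: CensoringScheme | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size == 0:
            raise DatasetError(f"dataset {self.label!r} is empty")
        if np.any(t <= 0) or np.any(~np.isfinite(t)):
            raise DatasetError(f"dataset {self.label!r} contains non-positive times")
        if self.censoring is not None and len(t) != self.censoring.m:
            raise DatasetError(
                f"dataset {self.label!r} has {len(t)} times but the scheme expects "
                f"m = {self.censoring.m}"
            )

    @property
    def n_obs(self) -> int:
        return len(self.times)


# Surviving days of 72 guinea pigs injected with tubercle bacilli.
_GUINEA_COMPLETE = (
    12, 15, 22, 24, 24, 32, 32, 33, 34, 38, 38, 43, 44, 48, 52, 53, 54, 54,
    55, 56, 57, 58, 58, 59, 60, 60, 60, 60, 61, 62, 63, 65, 65, 67, 68, 70,
    70, 72, 73, 75, 76, 76, 81, 83, 84, 85, 87, 91, 95, 96, 98, 99, 109, 110,
    121, 127, 129, 131, 143, 146, 146, 175, 175, 211, 233, 258, 258, 263,
    297, 341, 341, 376,
)

# One published random grouping of the 72 values into 36 pairs (k = 2):
# the 36 group minima.  Stored verbatim; the grouping seed is unknown.
_GUINEA_FF36 = (
    12, 15, 22, 24, 32, 32, 33, 34, 38, 38, 43, 44, 48, 52, 54, 55, 56, 58,
    58, 60, 60, 61, 63, 65, 65, 68, 70, 70, 73, 76, 84, 91, 109, 110, 129, 143,
)

# Progressively censored subsamples of the 36 first-failure values
# (k = 2, n = 36, m = 18) under three removal schemes.
_GUINEA_R1 = (12, 24, 32, 32, 34, 38, 54, 55, 58, 60, 61, 65, 68, 70, 91, 109, 110, 143)
_GUINEA_R2 = (12, 15, 22, 24, 32, 32, 33, 34, 38, 43, 44, 54, 55, 58, 60, 65, 68, 70)
_GUINEA_R3 = (12, 15, 22, 24, 32, 32, 33, 34, 38, 38, 43, 44, 48, 52, 54, 55, 56, 58)


def _fixture(name: str) -> Dataset:
    if name == "guinea_complete":
        return Dataset(np.array(_GUINEA_COMPLETE, float), label=name)
    if name == "guinea_ff36":
        return Dataset(np.array(_GUINEA_FF36, float), label=name)
    schemes = {
        "guinea_R1": "(18, 0*17)",
        "guinea_R2": "(1*18)",
        "guinea_R3": "(0*17, 18)",
    }
    times = {"guinea_R1": _GUINEA_R1, "guinea_R2": _GUINEA_R2, "guinea_R3": _GUINEA_R3}
    if name in schemes:
        return Dataset(
            np.array(times[name], float),
            label=name,
            censoring=parse_scheme(schemes[name], k=2, n=36),
        )
    raise DatasetError(f"unknown fixture {name!r}")


FIXTURES = ("guinea_complete", "guinea_ff36", "guinea_R1", "guinea_R2", "guinea_R3")


def load_dataset(path_or_name, censoring: CensoringScheme | None = None) -> Dataset:
    """Load a dataset from a fixture name or a text/CSV file.

    File format: one positive time per line, or a single-column CSV with an
    optional non-numeric header line.  Load errors report the offending
    line number.
    """
    name = str(path_or_name)
    if name in FIXTURES:
        ds = _fixture(name)
        if censoring is not None:
            ds = Dataset(ds.times, label=ds.label, censoring=censoring)
        return ds
    path = Path(path_or_name)
    if not path.exists():
        raise DatasetError(f"no such file or fixture: {name!r}")
    times = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip().rstrip(",")
        if not line:
            continue
        for token in line.replace(",", " ").split():
            try:
                value = float(token)
            except ValueError:
                if lineno == 1 and not times:
                    break  # header line
                raise DatasetError(f"{path}:{lineno}: non-numeric entry {token!r}") from None
            if value <= 0:
                raise DatasetError(f"{path}:{lineno}: non-positive time {value}")
            times.append(value)
    if not times:
        raise DatasetError(f"{path}: no data found")
    return Dataset(np.array(times), label=path.stem, censoring=censoring)


def first_failure_grouping(data: Dataset, k: int, seed) -> Dataset:
    """Randomly partition complete data into groups of ``k``; return the minima.

    With ``k = 1`` this is the sorted identity; the total count must be
    divisible by ``k``.
    """
    N = data.n_obs
    if k < 1 or N % k != 0:
        raise DatasetError(f"sample size {N} is not divisible by group size {k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.times)
    minima = perm.reshape(N // k, k).min(axis=1)
    return Dataset(np.sort(minima), label=f"{data.label}_ff{N // k}")
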