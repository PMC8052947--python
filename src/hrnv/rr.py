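"""RR-interval series and derived HRnV sequences.

Heart rate n-variability (HRnV) generalises HRV by analysing sequences of
n-beat aggregated RR intervals.  Two constructions exist:

* ``RRnI`` — non-overlapping windows: consecutive sums of n beats, windows
  advancing n beats at a time (the overlap stride ``m`` is 0 by convention).
* ``RRnI_m`` — overlapping windows: n-beat sums whose start positions advance
  by ``m`` beats (1 ≤ m ≤ n−1), so successive windows share n−m beats.

HRV is the n = 1 special case.  With a maximum order of 3 this yields the six
canonical streams HRV, HR2V, HR2V1, HR3V, HR3V1, HR3V2, in that fixed order.

Inputs are assumed to be clean sinus-rhythm series; no ectopic-beat or
artifact correction is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RRSeries",
    "DerivedRRSequence",
    "build_rrni",
    "build_rrni_m",
    "enumerate_streams",
    "stream_label",
    "read_rr_file",
    "write_rr_file",
    "read_manifest",
]


class InvalidRRInputError(ValueError):
    """Raised when an RR series or derivation parameter violates a precondition."""


@dataclass(frozen=True)
class RRSeries:
    """A single patient's consecutive RR intervals in milliseconds."""

    patient_id: str
    intervals: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidRRInputError(
                f"RR series '{self.patient_id}' must be a 1-D sequence of length >= 2, "
                f"got shape {arr.shape}"
            )
        if not np.all(arr > 0):
            raise InvalidRRInputError(
                f"RR series '{self.patient_id}' contains non-positive intervals"
            )
        object.__setattr__(self, "intervals", arr)

    @property
    def duration_s(self) -> float:
        """Total recording duration in seconds."""
        return float(self.intervals.sum() / 1000.0)

    def __len__(self) -> int:
        return self.intervals.size


@dataclass(frozen=True)
class DerivedRRSequence:
    """An aggregated RR sequence (RRnI or RRnI_m) derived from a source series.

    ``m == 0`` denotes the non-overlapping RRnI construction; ``m >= 1`` the
    overlapping RRnI_m construction with stride m.
    """

    source_id: str
    n: int
    m: int
    values: np.ndarray
    stream_label: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not self.stream_label:
            object.__setattr__(self, "stream_label", stream_label(self.n, self.m))

    def __len__(self) -> int:
        return self.values.size


def stream_label(n: int, m: int) -> str:
    """Canonical stream name: HRV for n=1, else HR{n}V or HR{n}V{m}."""
    if n == 1:
        return "HRV"
    return f"HR{n}V" if m == 0 else f"HR{n}V{m}"


def build_rrni(rr: RRSeries, n: int) -> DerivedRRSequence:
    """Non-overlapping n-beat aggregation: values[k] = sum of beats kn .. kn+n-1.

    Trailing beats that do not fill a complete window are dropped, so the
    output has floor(len/n) values.  n = 1 reproduces the source exactly.
    """
    if n < 1:
        raise InvalidRRInputError(f"aggregation order n must be >= 1, got {n}")
    if len(rr) < n:
        raise InvalidRRInputError(
            f"series of length {len(rr)} shorter than window n={n}"
        )
    k = len(rr) // n
    vals = rr.intervals[: k * n].reshape(k, n).sum(axis=1)
    return DerivedRRSequence(source_id=rr.patient_id, n=n, m=0, values=vals)


def build_rrni_m(rr: RRSeries, n: int, m: int) -> DerivedRRSequence:
    """Overlapping n-beat aggregation with stride m: values[k] = sum of beats km .. km+n-1.

    Requires 1 <= m <= n-1; output length is floor((len-n)/m) + 1.
    """
    if n < 2:
        raise InvalidRRInputError(f"overlapping windows require n >= 2, got n={n}")
    if not 1 <= m <= n - 1:
        raise InvalidRRInputError(
            f"overlap stride m must lie in [1, n-1] = [1, {n - 1}], got m={m}"
        )
    if len(rr) < n:
        raise InvalidRRInputError(
            f"series of length {len(rr)} shorter than window n={n}"
        )
    starts = np.arange(0, len(rr) - n + 1, m)
    csum = np.concatenate([[0.0], np.cumsum(rr.intervals)])
    vals = csum[starts + n] - csum[starts]
    return DerivedRRSequence(source_id=rr.patient_id, n=n, m=m, values=vals)


def enumerate_streams(rr: RRSeries, max_n: int = 3) -> list[DerivedRRSequence]:
    """All derived streams up to order ``max_n``, in canonical order.

    For max_n = 3: HRV, HR2V, HR2V1, HR3V, HR3V1, HR3V2 (six streams).
    """
    if max_n < 1:
        raise InvalidRRInputError(f"max_n must be >= 1, got {max_n}")
    streams = [build_rrni(rr, 1)]
    for n in range(2, max_n + 1):
        streams.append(build_rrni(rr, n))
        for m in range(1, n):
            streams.append(build_rrni_m(rr, n, m))
    return streams


# ---------------------------------------------------------------------------
# File interfaces: one RR interval (ms) per line, optional "rr_ms" header;
# a manifest CSV maps patient_id -> file path.
# ---------------------------------------------------------------------------

def read_rr_file(path: str | Path, patient_id: str | None = None) -> RRSeries:
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if lines and lines[0].lower() in {"rr_ms", "rr", "rr_interval_ms"}:
        lines = lines[1:]
    try:
        vals = np.array([float(x) for x in lines])
    except ValueError as exc:
        raise InvalidRRInputError(f"non-numeric RR value in {path}: {exc}") from exc
    return RRSeries(patient_id=patient_id or path.stem, intervals=vals)


def write_rr_file(rr: RRSeries, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("rr_ms\n")
        for v in rr.intervals:
            fh.write(f"{v:.10g}\n")


def read_manifest(path: str | Path) -> Iterable[RRSeries]:
    """Yield RRSeries for every (patient_id, path) row of a manifest CSV."""
    manifest = pd.read_csv(path)
    base = Path(path).parent
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        yield read_rr_file(p, patient_id=str(row["patient_id"]))
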