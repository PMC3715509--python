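"""Temporal contact sequences: the data model, I/O and whole-sequence statistics.

A contact sequence is an ordered multiset of timestamped, undirected contacts
(i, j, t) between individuals.  It is the raw object on which both the disease
simulation and every static-network representation operate.  Times are discrete
(integers, in the data's native timestep) and are shifted on construction so
that the first contact happens at t = 0; the total sampling time ``T`` is then
the time of the last contact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np

__all__ = [
    "ContactSequence",
    "ContactDataError",
    "UndefinedStatisticError",
    "read_contacts",
    "write_contacts",
    "interevent_times",
    "burstiness",
]


class ContactDataError(ValueError):
    """Malformed or invalid contact data."""


class UndefinedStatisticError(ValueError):
    """A statistic was requested on data that cannot define it."""


@dataclass(frozen=True)
class ContactSequence:
    """A canonical temporal network.

    Attributes
    ----------
    i, j : int64 arrays
        Dense vertex indices of each contact, oriented so the label of ``i``
        sorts before the label of ``j`` (one canonical orientation per pair).
    t : int64 array
        Contact times, shifted so ``t.min() == 0`` and sorted non-decreasing.
    labels : tuple of str
        Original vertex labels; index ``v`` in ``i``/``j`` refers to
        ``labels[v]``.  Every vertex takes part in at least one contact.
    """

    i: np.ndarray
    j: np.ndarray
    t: np.ndarray
    labels: tuple[str, ...]

    # -- basic quantities ---------------------------------------------------
    @property
    def N(self) -> int:
        """Number of distinct vertices."""
        return len(self.labels)

    @property
    def L(self) -> int:
        """Number of contacts."""
        return len(self.t)

    @property
    def T(self) -> int:
        """Total sampling time (time of the last contact; first is at 0)."""
        return int(self.t[-1]) if self.L else 0

    @property
    def pairs(self) -> set[tuple[int, int]]:
        """Set E of vertex-index pairs (canonical orientation) with >= 1 contact."""
        return set(zip(self.i.tolist(), self.j.tolist()))

    def _pair_keys(self) -> np.ndarray:
        return self.i.astype(np.int64) * self.N + self.j

    @property
    def M(self) -> int:
        """Number of distinct contacted pairs, |E|."""
        return len(np.unique(self._pair_keys()))

    @property
    def E(self) -> set[tuple[str, str]]:
        """Distinct contacted pairs as label tuples (canonical label order)."""
        out = set()
        for a, b in zip(self.i.tolist(), self.j.tolist()):
            la, lb = self.labels[a], self.labels[b]
            out.add((la, lb) if la <= lb else (lb, la))
        return out

    def first_contact_time(self) -> np.ndarray:
        """Per-vertex time of first contact (int64 array of length N)."""
        first = np.full(self.N, np.iinfo(np.int64).max, dtype=np.int64)
        np.minimum.at(first, self.i, self.t)
        np.minimum.at(first, self.j, self.t)
        return first

    def triples(self) -> list[tuple[str, str, int]]:
        """Contacts as (label_i, label_j, t) with labels in canonical order."""
        out = []
        for a, b, tt in zip(self.i.tolist(), self.j.tolist(), self.t.tolist()):
            la, lb = self.labels[a], self.labels[b]
            if lb < la:
                la, lb = lb, la
            out.append((la, lb, tt))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContactSequence):
            return NotImplemented
        return sorted(self.triples()) == sorted(other.triples())

    def __hash__(self):  # frozen dataclass would autogenerate an invalid one
        return hash(tuple(sorted(self.triples())))

    # -- construction -------------------------------------------------------
    @staticmethod
    def from_triples(rows: Iterable[tuple[str, str, int]]) -> "ContactSequence":
        """Build a canonical sequence from (i, j, t) triples.

        Vertex labels are opaque strings mapped to dense indices in order of
        first appearance.  Times must be integers; the origin is shifted to
        the first contact.  Duplicate rows are kept (several contacts between
        one pair in one timestep are legal).
        """
        index: dict[str, int] = {}
        ii, jj, tt = [], [], []
        for n, row in enumerate(rows, start=1):
            try:
                a, b, t = row
            except (TypeError, ValueError):
                raise ContactDataError(f"row {n}: expected (i, j, t), got {row!r}")
            a, b = str(a), str(b)
            if isinstance(t, float) and not float(t).is_integer():
                raise ContactDataError(f"row {n}: non-integer time {t!r}")
            try:
                t = int(t)
            except (TypeError, ValueError):
                raise ContactDataError(f"row {n}: non-integer time {t!r}")
            if t < 0:
                raise ContactDataError(f"row {n}: negative time {t}")
            if a == b:
                raise ContactDataError(f"row {n}: self-contact {a!r}")
            for lab in (a, b):
                if lab not in index:
                    index[lab] = len(index)
            if a > b:  # canonical orientation by label, so storage (and the
                a, b = b, a  # per-run tie shuffling) ignores input row order
            ii.append(index[a])
            jj.append(index[b])
            tt.append(t)
        if not ii:
            raise ContactDataError("empty contact sequence")
        i = np.asarray(ii, dtype=np.int64)
        j = np.asarray(jj, dtype=np.int64)
        t = np.asarray(tt, dtype=np.int64)
        t = t - t.min()
        labels = tuple(sorted(index, key=index.get))
        lab_arr = np.asarray(labels, dtype=object)
        order = np.lexsort((lab_arr[j], lab_arr[i], t))
        return ContactSequence(i=i[order], j=j[order], t=t[order], labels=labels)


# ---------------------------------------------------------------------------
# I/O: plain-text three-column contact lists ("i j t", '#' comments ignored)
# ---------------------------------------------------------------------------

def read_contacts(source: IO[str] | str) -> ContactSequence:
    """Read a contact sequence from a three-column text stream or path.

    Each non-comment line holds ``i j t`` separated by whitespace.  Raises
    :class:`ContactDataError` naming the offending line on malformed rows,
    self-contacts or empty input.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return read_contacts(fh)
    rows = []
    for lineno, line in enumerate(source, start=1):
        text = line.split("#", 1)[0].strip()
        if not text:
            continue
        parts = text.split()
        if len(parts) != 3:
            raise ContactDataError(f"line {lineno}: expected 3 columns, got {len(parts)}")
        a, b, t_str = parts
        try:
            t = int(t_str)
        except ValueError:
            raise ContactDataError(f"line {lineno}: non-integer time {t_str!r}")
        if a == b:
            raise ContactDataError(f"line {lineno}: self-contact {a!r}")
        rows.append((a, b, t))
    if not rows:
        raise ContactDataError("empty contact list")
    return ContactSequence.from_triples(rows)


def write_contacts(cs: ContactSequence, sink: IO[str] | str) -> None:
    """Write a contact sequence as a three-column text table.

    ``read_contacts(write_contacts(cs))`` reproduces ``cs`` exactly, and the
    output is a deterministic function of the sequence (two writes of the
    same sequence are byte-identical).
    """
    if isinstance(sink, str):
        with open(sink, "w") as fh:
            write_contacts(cs, fh)
        return
    rows = sorted(cs.triples(), key=lambda r: (r[2], r[0], r[1]))
    for a, b, tt in rows:
        sink.write(f"{a}\t{b}\t{tt}\n")


# ---------------------------------------------------------------------------
# Temporal statistics
# ---------------------------------------------------------------------------

def interevent_times(cs: ContactSequence) -> np.ndarray:
    """Pooled interevent times.

    For every pair of vertices with two or more contacts, the successive
    time differences of that pair's contacts, concatenated over all pairs.
    Pairs with a single contact contribute nothing; the result may be empty.
    """
    keys = cs._pair_keys()
    order = np.lexsort((cs.t, keys))
    k = keys[order]
    t = cs.t[order]
    dt = np.diff(t)
    same_pair = k[1:] == k[:-1]
    return dt[same_pair].astype(np.int64)


def burstiness(cs: ContactSequence, mode: str = "goh") -> float:
    """Burstiness of the pooled interevent-time series.

    With ``mode="goh"`` (default) returns the normalised dispersion
    B = (sigma - m) / (sigma + m), bounded in [-1, 1]: -1 for a perfectly
    periodic series, 0 for Poissonian (exponential) statistics, approaching
    1 for extremely bursty trains.  ``mode="cv"`` returns the raw
    coefficient of variation sigma / m instead.
    """
    if mode not in ("goh", "cv"):
        raise ValueError(f"unknown burstiness mode {mode!r}")
    dt = interevent_times(cs)
    if len(dt) < 2:
        raise UndefinedStatisticError(
            f"burstiness needs >= 2 interevent times, got {len(dt)}"
        )
    m = float(np.mean(dt))
    sigma = float(np.std(dt))
    if mode == "cv":
        return sigma / m
    return (sigma - m) / (sigma + m)
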