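"""Reading, writing and partitioning of contact-event streams.

The on-disk convention follows the SocioPatterns "tij" format: one line per
detected contact, ``timestamp i j [extra ...]``, where a contact between
individuals *i* and *j* was recorded during the time step ending at
``timestamp``.  Proximity sensors in those deployments report every 20
seconds, which defines the unit time step; internally all timestamps are
rescaled to consecutive positive integer steps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

__all__ = [
    "ContactEventList",
    "CommunityMap",
    "read_tij",
    "write_tij",
    "read_communities",
    "write_communities",
    "partition_days",
]


def _canonical_pair(i, j):
    """Unordered pair as a sorted tuple (labels must be mutually comparable)."""
    return (i, j) if i <= j else (j, i)


@dataclass(frozen=True)
class ContactEventList:
    """A temporal network as a list of timestamped undirected contact events.

    Parameters
    ----------
    events
        Sorted tuples ``(t, i, j)`` with 1-based integer step ``t`` and
        ``i < j`` (canonical unordered pair).  The same pair may appear at
        many steps but at most once per step.
    step_seconds
        Wall-clock duration of one time step (20 s for SocioPatterns data).
    """

    events: tuple = ()
    step_seconds: float = 20.0
    extra_nodes: frozenset = field(default_factory=frozenset)

    @staticmethod
    def from_records(records: Iterable[tuple], step_seconds: float = 20.0,
                     extra_nodes: Iterable = ()) -> "ContactEventList":
        """Build a valid event list from possibly unsorted/duplicated records.

        Self-contacts (``i == j``) are dropped with a logged count; duplicate
        ``(t, i, j)`` records collapse to one, since link activity is binary
        per step.
        """
        seen = set()
        n_self = 0
        for t, i, j in records:
            t = int(t)
            if t < 1:
                raise ValueError(f"time step must be a positive integer, got {t}")
            if i == j:
                n_self += 1
                continue
            seen.add((t,) + _canonical_pair(i, j))
        if n_self:
            log.warning("dropped %d self-contact record(s)", n_self)
        evs = tuple(sorted(seen, key=lambda e: (e[0], str(e[1]), str(e[2]))))
        return ContactEventList(evs, step_seconds, frozenset(extra_nodes))

    @property
    def node_set(self) -> frozenset:
        nodes = {n for _, i, j in self.events for n in (i, j)}
        return frozenset(nodes) | self.extra_nodes

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def max_time(self) -> int:
        return self.events[-1][0] if self.events else 0

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass(frozen=True)
class CommunityMap:
    """Node -> community-label assignment (e.g. school classes, wards)."""

    assignment: Mapping

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, nodes: Iterable) -> dict:
        missing = [n for n in nodes if n not in self.assignment]
        if missing:
            raise KeyError(f"nodes without community label: {missing[:5]}")
        return {n: self.assignment[n] for n in nodes}

    def groups(self) -> dict:
        out: dict = {}
        for node, label in self.assignment.items():
            out.setdefault(label, set()).add(node)
        return out


def read_tij(path, step_seconds: float = 20.0) -> ContactEventList:
    """Read a whitespace-separated tij contact file.

    Raw timestamps are divided by ``step_seconds`` when every timestamp in
    the file is a multiple of it; otherwise they are taken verbatim as unit
    steps.  Columns beyond the third (class/role metadata in some dialects)
    are ignored.  If the rescaled minimum step is below 1 the whole stream is
    shifted so it starts at step 1.
    """
    raw: list[tuple[int, str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 fields, got {len(parts)}")
            try:
                t_raw = int(float(parts[0]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad timestamp {parts[0]!r}") from exc
            raw.append((t_raw, parts[1], parts[2]))
    if not raw:
        return ContactEventList((), step_seconds)
    step = int(step_seconds)
    if step > 1 and all(t % step == 0 for t, _, _ in raw):
        raw = [(t // step, i, j) for t, i, j in raw]
    t_min = min(t for t, _, _ in raw)
    if t_min < 1:
        raw = [(t - t_min + 1, i, j) for t, i, j in raw]
    return ContactEventList.from_records(raw, step_seconds)


def write_tij(events: ContactEventList, path) -> None:
    """Write a tij file that :func:`read_tij` inverts exactly.

    One line per event, ``t*step_seconds i j``, sorted by time then pair.
    """
    path = Path(path)
    step = int(events.step_seconds)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t, i, j in events.events:
            fh.write(f"{t * step} {i} {j}\n")


def read_communities(path) -> CommunityMap:
    """Read a two-column metadata file ``node community_label``."""
    assignment = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            assignment[parts[0]] = parts[1]
    return CommunityMap(assignment)


def write_communities(communities: CommunityMap, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for node in sorted(communities.assignment, key=str):
            fh.write(f"{node} {communities.assignment[node]}\n")


def partition_days(events: ContactEventList, steps_per_day: int) -> list[ContactEventList]:
    """Split an event stream into consecutive days of ``steps_per_day`` steps.

    Day ``d`` (1-based) receives events with ``t`` in
    ``((d-1)*steps_per_day, d*steps_per_day]``, re-indexed so each day starts
    at local step 1.  Empty days are preserved as empty lists.  Empirical
    deployments have irregular active hours, so the day length is an explicit
    caller-supplied convention rather than a wall-clock rule.
    """
    if steps_per_day < 1:
        raise ValueError("steps_per_day must be >= 1")
    if not events.events:
        return []
    n_days = math.ceil(events.max_time / steps_per_day)
    buckets: list[list] = [[] for _ in range(n_days)]
    for t, i, j in events.events:
        d = (t - 1) // steps_per_day
        buckets[d].append((t - d * steps_per_day, i, j))
    return [
        ContactEventList(tuple(b), events.step_seconds)
        for b in buckets
    ]
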