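"""Frequent sequential pattern mining over PSAV state sequences.

Patterns are time-ordered but not necessarily consecutive state
subsequences. Support of a pattern within a class is the fraction of that
class's sequences containing it (each sequence counted at most once,
``counting_mode="per_sequence"``); an alternative ``"per_instance"`` mode
counts non-overlapping occurrences against the total number of state
instances, matching the frequency bookkeeping of the length-one
walkthrough convention.

The miner is PrefixSpan (pattern growth with pseudo-projected databases).
:func:`brute_force_patterns` enumerates every candidate tuple and serves as
an independent verification oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator

from .transform import StateSequence


@dataclass(frozen=True)
class Pattern:
    """An ordered tuple of state labels with its class of origin and support."""

    states: tuple[str, ...]
    class_origin: str | None = None
    support: float = 0.0
    instance_count: int = 0
    scheme: str | None = None  # name of the discretization scheme of origin

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("pattern must have at least one state")

    def __str__(self) -> str:
        return "→".join(self.states)


def _states_of(seq) -> tuple[str, ...]:
    return tuple(seq.states) if isinstance(seq, StateSequence) else tuple(seq)


def contains(sequence, pattern) -> bool:
    """True iff the pattern is a (not necessarily contiguous) subsequence."""
    pat = pattern.states if isinstance(pattern, Pattern) else tuple(pattern)
    states = _states_of(sequence)
    it = iter(states)
    return all(any(s == p for s in it) for p in pat)


def count_occurrences(sequence, pattern) -> int:
    """Number of non-overlapping, leftmost-greedy occurrences of the pattern."""
    pat = pattern.states if isinstance(pattern, Pattern) else tuple(pattern)
    states = _states_of(sequence)
    count = pos = 0
    while True:
        j = pos
        for p in pat:
            while j < len(states) and states[j] != p:
                j += 1
            if j >= len(states):
                return count
            j += 1
        count += 1
        pos = j


def _sort_patterns(patterns: list[Pattern]) -> list[Pattern]:
    # deterministic: by length, then descending support, then lexicographic
    return sorted(patterns, key=lambda p: (len(p.states), -p.support, p.states))


def _mine_per_sequence(seqs: list[tuple[str, ...]], min_support: float,
                       max_length: int) -> list[Pattern]:
    n = len(seqs)
    if n == 0:
        return []
    out: list[Pattern] = []

    def recurse(prefix: tuple[str, ...], proj: list[tuple[int, int]]) -> None:
        # proj: (sequence index, start position of its projected suffix)
        item_sids: dict[str, list[tuple[int, int]]] = {}
        for sid, pos in proj:
            seen: set[str] = set()
            seq = seqs[sid]
            for j in range(pos, len(seq)):
                it = seq[j]
                if it not in seen:
                    seen.add(it)
                    item_sids.setdefault(it, []).append((sid, j + 1))
        for item in sorted(item_sids):
            occs = item_sids[item]
            if len(occs) / n + 1e-9 < min_support:
                continue
            pat = prefix + (item,)
            out.append(Pattern(states=pat, support=len(occs) / n,
                               instance_count=len(occs)))
            if len(pat) < max_length:
                recurse(pat, occs)

    recurse((), [(i, 0) for i in range(n)])
    return _sort_patterns(out)


def _mine_per_instance(seqs: list[tuple[str, ...]], min_support: float,
                       max_length: int) -> list[Pattern]:
    # frequency denominator: total number of state instances in the class
    total = sum(len(s) for s in seqs)
    if total == 0:
        return []
    # enumerate candidates via the per-sequence lattice at support > 0, then
    # re-count occurrences per instance
    cands = _mine_per_sequence(seqs, 1e-9, max_length)
    out = []
    for p in cands:
        cnt = sum(count_occurrences(s, p) for s in seqs)
        freq = cnt / total
        if freq + 1e-9 >= min_support:
            out.append(Pattern(states=p.states, support=freq, instance_count=cnt))
    return _sort_patterns(out)


def prefixspan(sequences: Iterable, min_support: float = 0.3,
               max_length: int = 3, counting_mode: str = "per_sequence") -> list[Pattern]:
    """Mine all patterns with support >= ``min_support`` and length <= ``max_length``.

    Parameters
    ----------
    sequences : iterable of StateSequence or of label tuples
    min_support : float in (0, 1]
        Minimum fraction of sequences containing the pattern (or minimum
        instance frequency under ``per_instance``).
    max_length : int
        Maximum pattern length.
    counting_mode : {"per_sequence", "per_instance"}

    Returns
    -------
    list of Pattern, sorted by (length, descending support, states).
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    seqs = [_states_of(s) for s in sequences]
    if counting_mode == "per_sequence":
        return _mine_per_sequence(seqs, min_support, max_length)
    if counting_mode == "per_instance":
        return _mine_per_instance(seqs, min_support, max_length)
    raise ValueError(f"unknown counting_mode {counting_mode!r}")


def brute_force_patterns(sequences: Iterable, min_support: float = 0.3,
                         max_length: int = 3, counting_mode: str = "per_sequence",
                         cap: int = 200_000) -> list[Pattern]:
    """Exhaustive-enumeration oracle with the same contract as :func:`prefixspan`."""
    seqs = [_states_of(s) for s in sequences]
    alphabet = sorted({s for seq in seqs for s in seq})
    n_cands = sum(len(alphabet) ** l for l in range(1, max_length + 1))
    if n_cands > cap:
        raise ValueError(f"candidate space {n_cands} exceeds cap {cap}")
    n = len(seqs)
    total = sum(len(s) for s in seqs)
    out: list[Pattern] = []
    for length in range(1, max_length + 1):
        for states in product(alphabet, repeat=length):
            if counting_mode == "per_sequence":
                cnt = sum(contains(s, states) for s in seqs)
                denom = n
            else:
                cnt = sum(count_occurrences(s, states) for s in seqs)
                denom = total
            if denom and cnt / denom + 1e-9 >= min_support and cnt > 0:
                out.append(Pattern(states=states, support=cnt / denom,
                                   instance_count=cnt))
    return _sort_patterns(out)


class PrefixSpanMiner(BaseEstimator):
    """Estimator wrapper around :func:`prefixspan`.

    After ``fit(sequences)``, the mined patterns are in ``patterns_``.
    """

    def __init__(self, min_support: float = 0.3, max_length: int = 3,
                 counting_mode: str = "per_sequence"):
        self.min_support = min_support
        self.max_length = max_length
        self.counting_mode = counting_mode

    def fit(self, X, y=None):
        self.patterns_ = prefixspan(X, self.min_support, self.max_length,
                                    self.counting_mode)
        return self

    def fit_predict(self, X, y=None) -> list[Pattern]:
        return self.fit(X).patterns_


def mine_class_patterns(state_sequences: Sequence[StateSequence],
                        min_support: float = 0.3, max_length: int = 3,
                        counting_mode: str = "per_sequence",
                        scheme: str | None = None) -> tuple[list[Pattern], list[Pattern]]:
    """Mine each outcome class separately.

    Empty state sequences are excluded from both the numerator and the
    denominator of support. Returns ``(nonevent_patterns, event_patterns)``
    tagged with their class of origin.
    """
    by_class: dict[str, list[StateSequence]] = {"nonevent": [], "event": []}
    for s in state_sequences:
        if len(s) == 0:
            continue
        if s.class_label not in by_class:
            raise ValueError(f"unknown class label {s.class_label!r}")
        by_class[s.class_label].append(s)

    def tag(patterns: list[Pattern], cls: str) -> list[Pattern]:
        return [Pattern(states=p.states, class_origin=cls, support=p.support,
                        instance_count=p.instance_count, scheme=scheme)
                for p in patterns]

    non = prefixspan(by_class["nonevent"], min_support, max_length, counting_mode) \
        if by_class["nonevent"] else []
    eve = prefixspan(by_class["event"], min_support, max_length, counting_mode) \
        if by_class["event"] else []
    return tag(non, "nonevent"), tag(eve, "event")
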