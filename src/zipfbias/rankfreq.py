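"""Rank-frequency data structures, text pipeline, distances and file I/O.

The universal input to every estimator in this package is a
:class:`RankFrequencyCounts`: event counts sorted from most to least
frequent, indexed by *empirical* rank r_e = 1, 2, .... For word data the
counts come from a cleaned, whitespace-tokenized text; for simulations they
come from :func:`zipfbias.models.sample_counts`.

Because empirical ranks are extracted from the same sample as the counts,
they are correlated with the frequencies — the central fact that makes the
identity-permutation ("leading term") likelihood biased and motivates both
the full permutation-sum likelihood and the ABC estimators.
"""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ._errors import DomainError, ParseError

__all__ = [
    "RankFrequencyCounts",
    "RankMapping",
    "counts_from_tokens",
    "clean_text",
    "wasserstein_distance",
    "read_counts",
    "write_counts",
    "read_tokens",
]


@dataclass(frozen=True)
class RankFrequencyCounts:
    """Sorted event counts n(r_e), the empirical rank-frequency data.

    ``counts[r-1]`` is the count of the r-th most common event. Counts are
    positive and non-increasing; N is the total number of observations and
    W_obs the number of distinct observed events. An empty instance
    (N = 0, W_obs = 0) is permitted so the text pipeline can report empty
    inputs gracefully; estimators reject it.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1:
            raise DomainError("counts must be a 1-D vector")
        if c.size and (np.any(c < 1) or np.any(np.diff(c) > 0)):
            raise DomainError("counts must be positive and non-increasing")
        object.__setattr__(self, "counts", c)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def W_obs(self) -> int:
        return int(self.counts.size)

    def __len__(self) -> int:
        return self.W_obs

    def __getitem__(self, r):
        return self.counts[r]

    def __eq__(self, other) -> bool:
        return isinstance(other, RankFrequencyCounts) and np.array_equal(
            self.counts, other.counts)

    def __hash__(self):
        return hash(self.counts.tobytes())

    def padded(self, W: int) -> np.ndarray:
        """Counts zero-padded to length W >= W_obs (unobserved events)."""
        if W < self.W_obs:
            raise DomainError(f"W={W} < W_obs={self.W_obs}")
        out = np.zeros(W, dtype=np.int64)
        out[: self.W_obs] = self.counts
        return out


@dataclass(frozen=True)
class RankMapping:
    """A permutation s with s(r_p) = r_e, mapping probability ranks to
    empirical ranks; a member of the symmetric group S(W)."""

    s: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=np.int64)
        W = s.size
        if not np.array_equal(np.sort(s), np.arange(1, W + 1)):
            raise DomainError("mapping must be a permutation of 1..W")
        object.__setattr__(self, "s", s)

    @property
    def W(self) -> int:
        return int(self.s.size)

    @classmethod
    def identity(cls, W: int) -> "RankMapping":
        return cls(np.arange(1, W + 1))

    def __len__(self) -> int:
        return self.W

    def __getitem__(self, i):
        return self.s[i]


def counts_from_tokens(tokens: Iterable) -> RankFrequencyCounts:
    """Count distinct labels and sort non-increasing.

    Ties between equal counts keep first-occurrence order (which no
    likelihood in this package depends on).
    """
    counter = Counter(tokens)
    # Counter preserves insertion order; stable sort keeps first-occurrence
    # order among equal counts.
    counts = sorted(counter.values(), key=lambda c: -c)
    return RankFrequencyCounts(np.asarray(counts, dtype=np.int64))


# '#' is the number placeholder and must survive cleaning (so that the
# pipeline is idempotent); every other punctuation or symbol character goes.
_KEEP = {"#"}


def _strip_punct(text: str) -> str:
    return "".join(
        ch for ch in text
        if ch in _KEEP or unicodedata.category(ch)[0] not in ("P", "S")
    )


def clean_text(raw: str) -> list[str]:
    """Normalize raw text to a token sequence.

    Lowercases (Unicode casefold), removes punctuation and symbol
    characters (Unicode categories P* and S*), replaces every maximal
    digit run with a single ``#``, and splits on whitespace. Thousands
    separators are stripped before digit-run replacement, so "1,000"
    becomes a single ``#``.
    """
    text = _strip_punct(raw.casefold())
    text = re.sub(r"\d+", "#", text)
    return text.split()


def wasserstein_distance(
    a: RankFrequencyCounts,
    b: RankFrequencyCounts,
    *,
    pad: bool = True,
    log_counts: bool = False,
) -> float:
    """1-Wasserstein distance between two count vectors.

    The sorted count vectors are aligned rank-by-rank (the optimal quantile
    coupling in one dimension) and the mean absolute difference is
    returned. With ``pad=True`` (default) the shorter vector is extended
    with zero counts to the common length, so the distance "sees"
    differences in observed vocabulary size — precisely where unobserved
    tail events distort rank-frequency data. ``log_counts`` compares
    log1p-transformed counts instead (a sensitivity variant).
    """
    if a.W_obs == 0 or b.W_obs == 0:
        raise DomainError("wasserstein_distance requires non-empty counts")
    if pad:
        L = max(a.W_obs, b.W_obs)
        x = a.padded(L).astype(np.float64)
        y = b.padded(L).astype(np.float64)
    else:
        L = min(a.W_obs, b.W_obs)
        x = a.counts[:L].astype(np.float64)
        y = b.counts[:L].astype(np.float64)
    if log_counts:
        x = np.log1p(x)
        y = np.log1p(y)
    return float(np.abs(x - y).mean())


def mean_log_count(counts: RankFrequencyCounts) -> float:
    """Summary statistic for ABC regression: mean of ln(count) over the
    observed events."""
    if counts.W_obs == 0:
        raise DomainError("mean_log_count requires non-empty counts")
    return float(np.log(counts.counts.astype(np.float64)).mean())


# ---------------------------------------------------------------------------
# File I/O — plain-text formats only


def read_counts(path) -> RankFrequencyCounts:
    """Read counts from TSV ("event<TAB>count", optional header) or a file
    of one integer count per line. Counts are sorted on load."""
    values: list[int] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            field = line.split("\t")[-1] if "\t" in line else line.strip()
            try:
                value = int(field)
            except ValueError:
                if lineno == 1 and "\t" in line:
                    continue  # header row
                raise ParseError(f"expected an integer count, got {field!r}",
                                 line=lineno) from None
            if value < 1:
                raise ParseError(f"counts must be positive, got {value}",
                                 line=lineno)
            values.append(value)
    return RankFrequencyCounts(np.sort(np.asarray(values, dtype=np.int64))[::-1])


def write_counts(counts: RankFrequencyCounts, path) -> None:
    """Write one integer count per line, most frequent first.
    ``read_counts(write_counts(c)) == c``."""
    Path(path).write_text(
        "".join(f"{int(c)}\n" for c in counts.counts), encoding="utf-8")


def read_tokens(path) -> list[str]:
    """Read a UTF-8 text file and return its cleaned token sequence."""
    return clean_text(Path(path).read_text(encoding="utf-8"))
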