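"""Ordinal-pattern complexity: permutation entropy and permutation LZ complexity.

Both estimators first reduce the signal to a sequence of ordinal symbols:
each length-m delay vector ``(x(i), x(i+tau), ..., x(i+(m-1)tau))`` is
mapped to the permutation that sorts it ascending (ties broken by
earlier position first), one of m! patterns.

* Permutation entropy (PE) is the Shannon entropy (natural log) of the
  pattern relative frequencies, normalized by ln(m!) to [0, 1]: 0 for a
  monotone series, -> 1 for an i.i.d. series.
* Permutation Lempel-Ziv complexity (PLZC) runs the LZ76 phrase parser
  over the symbol sequence and normalizes the phrase count c(n) by the
  length-dependent upper bound: PLZC = c(n) * (log_{m!} n + 1) / n.
  Random sequences approach 1; regular sequences fall toward 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout import ElectrodeLayout, assign_regions
from .recording import Recording


@dataclass(frozen=True)
class EmbeddingParams:
    """Ordinal-embedding dimension m and time delay tau (samples)."""

    m: int = 4
    tau: int = 1

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("embedding dimension m must be >= 2")
        if self.tau < 1:
            raise ValueError("time delay tau must be >= 1 sample")


@dataclass
class OrdinalSymbolSequence:
    symbols: np.ndarray  # integers in [0, m!-1]
    m: int
    tau: int
    source_length: int

    def __len__(self) -> int:
        return len(self.symbols)


def embed(series, params: EmbeddingParams) -> np.ndarray:
    """Delay-embedded vectors: row i holds samples i, i+tau, ..., i+(m-1)tau."""
    x = np.asarray(series, dtype=float)
    m, tau = params.m, params.tau
    n = x.shape[0]
    k = n - (m - 1) * tau
    if k < 1:
        raise ValueError(
            f"series of length {n} too short for m={m}, tau={tau} "
            f"(needs at least {(m - 1) * tau + 1} samples)"
        )
    idx = np.arange(k)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def ordinal_index(vector) -> int:
    """Lexicographic index (Lehmer code) of a vector's ordinal pattern.

    The pattern is the argument order that sorts the vector ascending;
    equal values are ranked by earlier position first (stable sort).
    Bijective over tie-free vectors: all m! patterns get distinct indices
    in [0, m!-1].
    """
    v = np.asarray(vector, dtype=float)
    perm = np.argsort(v, kind="stable")
    return _lehmer_index(perm)


def _lehmer_index(perm: np.ndarray) -> int:
    m = len(perm)
    index = 0
    for i in range(m):
        smaller_after = int(np.sum(perm[i + 1:] < perm[i]))
        index += smaller_after * math.factorial(m - 1 - i)
    return index


def _symbols_vectorized(vectors: np.ndarray) -> np.ndarray:
    """Lehmer indices for every row of an embedded-vector matrix."""
    m = vectors.shape[1]
    perms = np.argsort(vectors, axis=1, kind="stable")
    codes = np.zeros(vectors.shape[0], dtype=np.int64)
    for i in range(m):
        smaller_after = (perms[:, i + 1:] < perms[:, i:i + 1]).sum(axis=1)
        codes += smaller_after * math.factorial(m - 1 - i)
    return codes


def symbolize(series, params: EmbeddingParams) -> OrdinalSymbolSequence:
    """Ordinal symbol sequence of a series (one symbol per delay vector)."""
    vectors = embed(series, params)
    _warn_if_undersampled(len(vectors), params)
    return OrdinalSymbolSequence(
        symbols=_symbols_vectorized(vectors),
        m=params.m,
        tau=params.tau,
        source_length=len(np.asarray(series)),
    )


def _warn_if_undersampled(n_patterns: int, params: EmbeddingParams) -> None:
    needed = 5 * math.factorial(params.m)
    if n_patterns < needed:
        warnings.warn(
            f"only {n_patterns} ordinal patterns for m={params.m} "
            f"(fewer than 5*m! = {needed}); pattern distribution may be undersampled",
            stacklevel=3,
        )


def _pattern_counts(symbols: np.ndarray, m: int) -> np.ndarray:
    return np.bincount(symbols, minlength=math.factorial(m))


def permutation_entropy(series, params: EmbeddingParams = EmbeddingParams()) -> float:
    """Normalized permutation entropy in [0, 1] (natural-log entropy / ln m!)."""
    seq = symbolize(series, params)
    return _pe_from_counts(_pattern_counts(seq.symbols, params.m))


def _pe_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        raise ValueError("no ordinal patterns to count")
    p = counts[counts > 0] / total
    if len(p) == 1:
        return 0.0
    h = float(-(p * np.log(p)).sum())
    return h / math.log(len(counts))


def lz_phrase_count(symbols) -> int:
    """LZ76 phrase count of a symbol sequence.

    Scans the sequence with the classic S/Q parser: the candidate phrase
    Q grows while it occurs as a substring of everything seen so far
    minus its own last character (SQv); each failure closes a phrase.
    A trailing incomplete phrase counts once. The count starts at 1 for
    the first symbol.
    """
    if isinstance(symbols, OrdinalSymbolSequence):
        symbols = symbols.symbols
    seq = np.asarray(symbols)
    n = len(seq)
    if n < 2:
        raise ValueError("symbol sequence must have length >= 2")
    s = "".join(chr(int(v)) for v in seq)  # C-speed substring search
    c = 1
    q_start, q_end = 1, 2  # Q = s[q_start:q_end]
    while q_end <= n:
        if s[q_start:q_end] in s[: q_end - 1]:  # Q a substring of SQv
            q_end += 1
        else:  # Q is new: close the phrase, start the next
            c += 1
            q_start = q_end
            q_end += 1
    if q_start < n:  # trailing incomplete phrase
        c += 1
    return c


def plzc(series, params: EmbeddingParams = EmbeddingParams()) -> float:
    """Permutation Lempel-Ziv complexity: c(n) * (log_{m!} n + 1) / n."""
    seq = symbolize(series, params)
    return _plzc_from_symbols(seq.symbols, params.m)


def _plzc_from_symbols(symbols: np.ndarray, m: int) -> float:
    n = len(symbols)
    c = lz_phrase_count(symbols)
    log_base = math.log(math.factorial(m))
    return c * (math.log(n) / log_base + 1.0) / n


def _masked_runs(mask: np.ndarray) -> list[slice]:
    """Contiguous runs of usable samples."""
    if mask.all():
        return [slice(0, len(mask))]
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [slice(a, b) for a, b in zip(edges[::2], edges[1::2])]


def _channel_complexity(x: np.ndarray, mask: np.ndarray,
                        params: EmbeddingParams) -> tuple[float, float] | None:
    """PE and PLZC of one channel restricted to artifact-free runs.

    Symbols are computed within each contiguous usable run (no patterns
    spanning masked gaps); pattern counts pool across runs for PE, and
    run symbols concatenate for the LZ parse.
    """
    min_len = (params.m - 1) * params.tau + 1
    pieces = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for run in _masked_runs(mask):
            if run.stop - run.start >= min_len:
                pieces.append(symbolize(x[run], params).symbols)
    if not pieces:
        return None
    symbols = np.concatenate(pieces)
    if len(symbols) < 2:
        return None
    _warn_if_undersampled(len(symbols), params)
    pe = _pe_from_counts(_pattern_counts(symbols, params.m))
    return pe, _plzc_from_symbols(symbols, params.m)


def complexity_table(
    recordings: list[Recording],
    layout: ElectrodeLayout,
    params: EmbeddingParams = EmbeddingParams(),
) -> pd.DataFrame:
    """Per channel-epoch PE and PLZC, with region labels, as a tidy table.

    Excluded epochs are skipped; an all-masked channel-epoch yields no
    row. Whole-brain / per-region values are means over this table's
    rows (see :func:`whole_brain_means`, :func:`region_means`).
    """
    rows = []
    for rec in recordings:
        if rec.excluded:
            continue
        regions = assign_regions(layout, rec.channel_labels)
        for i, label in enumerate(rec.channel_labels):
            result = _channel_complexity(rec.samples[i], rec.artifact_mask, params)
            if result is None:
                continue
            pe, lzc = result
            rows.append(
                {
                    "subject": rec.subject_id,
                    "condition": rec.condition,
                    "day": rec.day,
                    "epoch": rec.epoch,
                    "channel": label,
                    "region": regions[label],
                    "pe": pe,
                    "plzc": lzc,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "condition", "day", "epoch", "channel", "region", "pe", "plzc"],
    )


def whole_brain_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean PE/PLZC over all channels, per subject-condition."""
    return (
        table.groupby(["subject", "condition"])[["pe", "plzc"]].mean().reset_index()
    )


def region_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean PE/PLZC per (subject, condition, day, epoch, region)."""
    return (
        table.groupby(["subject", "condition", "day", "epoch", "region"])[["pe", "plzc"]]
        .mean()
        .reset_index()
    )
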