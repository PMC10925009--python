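"""Seeded storage/sequencing channel: i.i.d. per-base errors on oligo reads.

Each base of each read independently suffers an error with probability p;
the error type is drawn from a (substitution, deletion, insertion) mix that
defaults to (0.5, 0.25, 0.25) — substitutions make up half of all errors,
matching the dominant error mode of synthesis plus short-read sequencing.
Substituted bases are replaced uniformly by one of the three alternatives;
inserted bases are uniform over ACGT and placed after the erring position.
``reads_per_oligo`` independent copies of every oligo are emitted, shuffled
so that read order carries no index information.

An ``exact_counts`` mode plants exactly round(p·len) errors per read at
uniformly chosen distinct positions, for variance-matched experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import InvalidConfigError
from .packetizer import Oligo

__all__ = ["ChannelConfig", "ReadLog", "corrupt"]

_BASES = "ACGT"
_ALTERNATIVES = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass(frozen=True)
class ChannelConfig:
    """Error-channel parameters; fully reproducible from ``seed``."""

    error_rate: float = 0.01
    mix: tuple[float, float, float] = (0.5, 0.25, 0.25)  # sub, del, ins
    reads_per_oligo: int = 1
    seed: int = 0
    exact_counts: bool = False
    shuffle: bool = True

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0:
            raise InvalidConfigError(f"error_rate must be in [0,1], got {self.error_rate}")
        if len(self.mix) != 3 or any(f < 0 for f in self.mix):
            raise InvalidConfigError("mix must be three non-negative fractions")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise InvalidConfigError(f"mix must sum to 1, got {sum(self.mix)}")
        if self.reads_per_oligo < 1:
            raise InvalidConfigError("reads_per_oligo must be >= 1")


@dataclass(frozen=True)
class ReadLog:
    """Per-read accounting of the injected errors."""

    source_index: int
    n_substitutions: int
    n_deletions: int
    n_insertions: int

    @property
    def n_errors(self) -> int:
        return self.n_substitutions + self.n_deletions + self.n_insertions


def _corrupt_one(seq: str, config: ChannelConfig, rng: np.random.Generator):
    n = len(seq)
    if config.exact_counts:
        k = int(round(config.error_rate * n))
        err_pos = np.sort(rng.choice(n, size=min(k, n), replace=False)) if k else np.array([], dtype=int)
    else:
        err_pos = np.flatnonzero(rng.random(n) < config.error_rate)
    types = rng.choice(3, size=err_pos.size, p=config.mix)
    out = []
    counts = [0, 0, 0]
    err_iter = iter(zip(err_pos.tolist(), types.tolist()))
    nxt = next(err_iter, None)
    for i, base in enumerate(seq):
        if nxt is not None and nxt[0] == i:
            t = nxt[1]
            counts[t] += 1
            if t == 0:  # substitution
                out.append(_ALTERNATIVES[base][rng.integers(3)])
            elif t == 1:  # deletion
                pass
            else:  # insertion, after the erring position
                out.append(base)
                out.append(_BASES[rng.integers(4)])
            nxt = next(err_iter, None)
        else:
            out.append(base)
    return "".join(out), counts


def corrupt(
    pool: Iterable[Oligo | str],
    config: ChannelConfig,
    with_log: bool = False,
):
    """Produce error-bearing reads of every oligo in the pool.

    Returns a list of read sequences (oligo identity hidden), or
    ``(reads, logs)`` when ``with_log`` is set.  Identical configs produce
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    reads: list[str] = []
    logs: list[ReadLog] = []
    for src, item in enumerate(pool):
        seq = item.sequence if isinstance(item, Oligo) else str(item)
        for _ in range(config.reads_per_oligo):
            read, (ns, nd, ni) = _corrupt_one(seq, config, rng)
            reads.append(read)
            logs.append(ReadLog(src, ns, nd, ni))
    if config.shuffle:
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
        logs = [logs[i] for i in order]
    return (reads, logs) if with_log else reads
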