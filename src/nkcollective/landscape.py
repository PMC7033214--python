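"""NK fitness landscapes over binary solution strings.

An NK landscape assigns a payoff to every length-``N`` bit string.  Each
dimension ``i`` contributes a value drawn from a lookup table indexed by the
state of bit ``i`` and the bits of ``K`` other dimensions it depends on; the
raw payoff of a solution is the arithmetic mean of the ``N`` contributions.
``K`` tunes ruggedness: ``K = 0`` yields a single-peaked additive landscape,
larger ``K`` produces many local optima.

Payoffs are normalized by dividing every raw payoff by the maximal raw payoff
over all ``2**N`` solutions and then raising the ratio to the power of eight,
so the best solution scores exactly 1.0 and most solutions score close to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, ResourceGuardError

#: Exponent of the monotone payoff transform applied after max-normalization.
PAYOFF_EXPONENT = 8

#: Largest N for which exhaustive enumeration (2**N states) is permitted.
ENUMERATION_GUARD = 20

Solution = tuple[int, ...]


def as_rng(seed: int | np.random.Generator | np.random.SeedSequence | None) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def solution_to_index(bits: Sequence[int]) -> int:
    """Map a bit sequence to its integer index (bit i is the 2**i digit)."""
    idx = 0
    for i, b in enumerate(bits):
        if b:
            idx |= 1 << i
    return idx


def index_to_solution(index: int, n: int) -> Solution:
    """Inverse of :func:`solution_to_index`."""
    return tuple((index >> i) & 1 for i in range(n))


def solution_to_string(bits: Sequence[int]) -> str:
    """Serialize a solution as a left-to-right bit string, e.g. ``"0101"``."""
    return "".join(str(int(b)) for b in bits)


def string_to_solution(s: str) -> Solution:
    """Parse a bit string written by :func:`solution_to_string`."""
    if not s or any(c not in "01" for c in s):
        raise InvalidInputError(f"not a bit string: {s!r}")
    return tuple(int(c) for c in s)


@dataclass(frozen=True)
class NKLandscape:
    """A fully materialized NK landscape.

    Parameters
    ----------
    N : int
        Number of binary dimensions.
    K : int
        Number of other dimensions each dimension's contribution depends on,
        ``0 <= K <= N - 1``.
    interaction_map : ndarray of shape (N, K)
        Row ``i`` lists the ``K`` dimensions (excluding ``i``) whose bits
        enter dimension ``i``'s contribution table.
    contribution_tables : ndarray of shape (N, 2**(K+1))
        Row ``i`` maps each state of (own bit, linked bits) to a raw
        contribution in ``[0, 1]``.  The state index puts the own bit in the
        highest position and the linked bits, in ``interaction_map`` order,
        below it.
    seed : int or None
        Seed recorded at generation time (None for hand-built landscapes).
    topology : str
        ``"random"`` or ``"adjacent"`` interaction wiring.
    """

    N: int
    K: int
    interaction_map: np.ndarray
    contribution_tables: np.ndarray
    seed: int | None = None
    topology: str = "random"
    payoff_exponent: int = PAYOFF_EXPONENT
    # filled in __post_init__
    max_raw_payoff: float = field(init=False, default=0.0)
    _payoff_table: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        n, k = self.N, self.K
        imap = np.asarray(self.interaction_map, dtype=np.int64).reshape(n, k)
        tables = np.asarray(self.contribution_tables, dtype=np.float64).reshape(n, 2 ** (k + 1))
        for i in range(n):
            row = imap[i]
            if i in row or len(set(row.tolist())) != k:
                raise InvalidParameterError(
                    f"interaction_map[{i}] must hold {k} distinct dimensions != {i}"
                )
            if row.size and (row.min() < 0 or row.max() >= n):
                raise InvalidParameterError(f"interaction_map[{i}] out of range")
        object.__setattr__(self, "interaction_map", imap)
        object.__setattr__(self, "contribution_tables", tables)
        raw = self._raw_payoffs()
        max_raw = float(raw.max())
        object.__setattr__(self, "max_raw_payoff", max_raw)
        object.__setattr__(
            self, "_payoff_table", (raw / max_raw) ** self.payoff_exponent
        )

    def _raw_payoffs(self) -> np.ndarray:
        """Raw (pre-normalization) payoff of every solution, by exhaustive enumeration."""
        if self.N > ENUMERATION_GUARD:
            raise ResourceGuardError(
                f"N={self.N} exceeds the exhaustive-enumeration guard ({ENUMERATION_GUARD})"
            )
        m = 2**self.N
        idx = np.arange(m)
        bits = (idx[:, None] >> np.arange(self.N)) & 1  # (m, N)
        total = np.zeros(m)
        for i in range(self.N):
            state = bits[:, i] << self.K
            for j, partner in enumerate(self.interaction_map[i]):
                state = state | (bits[:, partner] << (self.K - 1 - j))
            total += self.contribution_tables[i, state]
        return total / self.N

    # -- evaluation ---------------------------------------------------------

    @property
    def solution_count(self) -> int:
        return 2**self.N

    def validate_solution(self, s: Sequence[int]) -> Solution:
        bits = tuple(int(b) for b in s)
        if len(bits) != self.N or any(b not in (0, 1) for b in bits):
            raise InvalidInputError(
                f"solution must be {self.N} bits of 0/1, got {s!r}"
            )
        return bits

    def payoff(self, s: Sequence[int]) -> float:
        """Normalized payoff of a solution: ``(raw/max_raw) ** 8`` in [0, 1]."""
        bits = self.validate_solution(s)
        return float(self._payoff_table[solution_to_index(bits)])

    def payoff_by_index(self, index: int) -> float:
        """Normalized payoff by integer solution index (no validation)."""
        return float(self._payoff_table[index])

    def all_payoffs(self) -> np.ndarray:
        """Normalized payoffs of all ``2**N`` solutions, indexed by solution index."""
        return self._payoff_table.copy()

    def enumerate_optima(self) -> tuple[Solution, int]:
        """Return ``(global optimum, number of local optima)``.

        A local optimum strictly beats all ``N`` single-bit-flip neighbours;
        the global optimum is the argmax of the payoff table (payoff 1.0).
        """
        p = self._payoff_table
        m = p.size
        neigh = p[np.arange(m)[:, None] ^ (1 << np.arange(self.N))]
        is_local = p > neigh.max(axis=1)
        best = int(p.argmax())
        return index_to_solution(best, self.N), int(is_local.sum())

    def random_solution(self, rng: np.random.Generator) -> Solution:
        return tuple(int(b) for b in rng.integers(0, 2, size=self.N))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "K": self.K,
            "topology": self.topology,
            "seed": self.seed,
            "payoff_exponent": self.payoff_exponent,
            "interaction_map": self.interaction_map.tolist(),
            "contribution_tables": self.contribution_tables.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NKLandscape":
        return cls(
            N=int(d["N"]),
            K=int(d["K"]),
            interaction_map=np.asarray(d["interaction_map"]),
            contribution_tables=np.asarray(d["contribution_tables"]),
            seed=d.get("seed"),
            topology=d.get("topology", "random"),
            payoff_exponent=int(d.get("payoff_exponent", PAYOFF_EXPONENT)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "NKLandscape":
        return cls.from_dict(json.loads(Path(path).read_text()))


def generate_landscape(
    N: int,
    K: int,
    rng: int | np.random.Generator | np.random.SeedSequence | None = None,
    topology: str = "random",
) -> NKLandscape:
    """Generate a seeded NK landscape.

    Contribution-table entries are i.i.d. Uniform(0, 1).  Under ``"random"``
    topology each dimension's ``K`` partners are drawn uniformly without
    replacement from the other dimensions; under ``"adjacent"`` they are the
    ``K`` following dimensions cyclically.
    """
    if N < 1:
        raise InvalidParameterError(f"N must be >= 1, got {N}")
    if not 0 <= K <= N - 1:
        raise InvalidParameterError(f"K must satisfy 0 <= K <= N-1, got K={K}, N={N}")
    seed = rng if isinstance(rng, int) else None
    gen = as_rng(rng)
    if topology == "random":
        imap = np.empty((N, K), dtype=np.int64)
        for i in range(N):
            others = np.delete(np.arange(N), i)
            imap[i] = gen.choice(others, size=K, replace=False)
    elif topology == "adjacent":
        imap = (np.arange(N)[:, None] + np.arange(1, K + 1)[None, :]) % N
    else:
        raise InvalidParameterError(f"unknown topology {topology!r}")
    tables = gen.uniform(0.0, 1.0, size=(N, 2 ** (K + 1)))
    return NKLandscape(
        N=N, K=K, interaction_map=imap, contribution_tables=tables,
        seed=seed, topology=topology,
    )


def enumerate_optima(landscape: NKLandscape) -> tuple[Solution, int]:
    """Module-level alias for :meth:`NKLandscape.enumerate_optima`."""
    return landscape.enumerate_optima()


def payoff(landscape: NKLandscape, s: Sequence[int]) -> float:
    """Module-level alias for :meth:`NKLandscape.payoff`."""
    return landscape.payoff(s)
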