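"""Monte-Carlo evaluation of integrity and anonymity.

Integrity experiments measure how often truncated hashes collide and how
reliably the collision-resolution machinery recovers: `collision_rate`
benchmarks a single raw hash function (the birthday problem over ``N``
slots), while `encoding_success` drives the full add sequence and records
the unrecoverable-collision rate and which hash types were needed.

Anonymity experiments simulate a *phonebook attack*: an adversary holding
the state file (assigned IDs plus coding tables) and a large candidate name
list computes every candidate's looked-up ID.  The number of candidate
names landing on each assigned ID is that participant's crowd of aliases;
its minimum over IDs is the k-anonymity of the encoding.

Name pools are either loaded from a plain-text list (one name per line) or
generated synthetically.  The synthetic generator emulates the structure of
a real person-name list — multi-part "Given Middle Family" names, pairwise
distinct after normalization by default, with optional controlled rates of
exact duplicates and phonetically identical spelling variants.
"""

from __future__ import annotations

import os
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidNameError, UnrecoverableCollisionError
from .hashing import DEFAULT_SALTS, dispatch_hash, double_hash
from .linker import (
    CodingConfig,
    Registry,
    _add_encoded,
    _lookup_encoded,
)
from .normalization import normalize

__all__ = [
    "AnonymityReport",
    "IntegrityResult",
    "NamePool",
    "SyntheticNameSpec",
    "build_registry",
    "collision_rate",
    "config_for_space",
    "encoding_success",
    "generate_name_pool",
    "load_name_list",
    "phonebook_attack",
    "sweep",
]


# ---------------------------------------------------------------------------
# Name pools
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class NamePool:
    """An ordered list of candidate names (participants and/or phonebook)."""

    names: list[str]
    source: str = "synthetic"
    _codecs: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.names:
            raise InvalidNameError("name pool is empty")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, i: int) -> str:
        return self.names[i]


def load_name_list(path: str | os.PathLike) -> NamePool:
    """Load a plain-text name list, one name per line (UTF-8).

    Lines are trimmed, blank lines dropped, order preserved and duplicates
    retained (they are meaningful for collision behavior).
    """
    with open(path, "r", encoding="utf-8") as fh:
        names = [line.strip() for line in fh]
    names = [n for n in names if n]
    if not names:
        raise InvalidNameError(f"name list {os.fspath(path)!r} contains no names")
    return NamePool(names=names, source=os.fspath(path))


@dataclass(frozen=True)
class SyntheticNameSpec:
    """Recipe for a synthetic name pool.

    ``duplicate_rate`` is the fraction of entries that are exact copies of
    another entry; ``phonetic_twin_rate`` the fraction that are spelled
    differently but identical after phonetic normalization.  The remaining
    entries are pairwise distinct after normalization.
    """

    size: int
    duplicate_rate: float = 0.0
    phonetic_twin_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise InvalidNameError("pool size must be >= 1")
        if self.duplicate_rate < 0 or self.phonetic_twin_rate < 0:
            raise InvalidNameError("rates must be non-negative")
        if self.duplicate_rate + self.phonetic_twin_rate >= 1:
            raise InvalidNameError("duplicate + twin rates must be < 1")


_ONSETS = (
    "b br c ch cl d dr f fl g gr h j k kr l m n p pr r s sh sk st t th tr v w y z"
).split()
_VOWELS = "a e i o u ai ei ia io ou".split()
_CODAS = ["", "", "", "n", "r", "s", "l", "m", "t", "d", "k", "nd", "ng", "rt"]

_VOWEL_SET = "aeiou"
_CLASSMATES = {  # same Soundex class, for spelling-variant construction
    "b": "pv", "p": "bv", "v": "bp", "f": "pv",
    "c": "ks", "g": "jq", "j": "gk", "k": "cq", "q": "kc", "s": "cz",
    "x": "zs", "z": "sx",
    "d": "t", "t": "d", "m": "n", "n": "m",
}


def _syllable(rng: random.Random) -> str:
    return rng.choice(_ONSETS) + rng.choice(_VOWELS) + rng.choice(_CODAS)


def _token(rng: random.Random, n_syllables: int) -> str:
    word = "".join(_syllable(rng) for _ in range(n_syllables))
    return word[0].upper() + word[1:]


def _person_name(rng: random.Random) -> str:
    given = _token(rng, rng.choice((1, 2, 2)))
    family = _token(rng, rng.choice((2, 2, 3)))
    # half the entries carry a middle part: an initial or a short name
    r = rng.random()
    if r < 0.25:
        middle = rng.choice("ABCDEFGHJKLMNPRSTW")
    elif r < 0.5:
        middle = _token(rng, 1)
    else:
        return f"{given} {family}"
    return f"{given} {middle} {family}"


def _phonetic_variant(name: str, rng: random.Random) -> str:
    """A different spelling with the identical normalized (phonetic) form.

    Mutations preserve per-token Soundex codes exactly: swapping a vowel
    for another vowel, substituting a non-leading consonant within its
    class, doubling a non-leading consonant, or appending a trailing vowel.
    """
    tokens = name.split(" ")
    candidates = [i for i, t in enumerate(tokens) if len(t) >= 3]
    ti = rng.choice(candidates if candidates else range(len(tokens)))
    token = tokens[ti]
    ops = []
    for pos in range(1, len(token)):
        ch = token[pos]
        if ch in _VOWEL_SET:
            ops.append(("vowel", pos))
        if ch in _CLASSMATES:
            ops.extend([("swap", pos), ("double", pos)])
    ops.append(("tail", len(token)))
    kind, pos = rng.choice(ops)
    if kind == "vowel":
        repl = rng.choice([v for v in _VOWEL_SET if v != token[pos]])
        token = token[:pos] + repl + token[pos + 1 :]
    elif kind == "swap":
        token = token[:pos] + rng.choice(_CLASSMATES[token[pos]]) + token[pos + 1 :]
    elif kind == "double":
        token = token[:pos] + token[pos] + token[pos:]
    else:
        token = token + ("e" if token[-1].lower() != "e" else "a")
    tokens[ti] = token
    return " ".join(tokens)


def _default_norm_config(
    sort_enabled: bool = True, phonetic_enabled: bool = True,
    salts: tuple[str, ...] = DEFAULT_SALTS,
) -> CodingConfig:
    # L is irrelevant for normalization; any valid value will do.
    return CodingConfig(
        L=1, sort_enabled=sort_enabled, phonetic_enabled=phonetic_enabled, salts=salts
    )


def generate_name_pool(spec: SyntheticNameSpec) -> NamePool:
    """Generate a reproducible synthetic pool per ``spec``.

    The base entries are rejection-sampled until pairwise distinct under
    the full default normalization (sorted, phonetic); duplicate and
    phonetic-twin entries are then injected at exactly
    ``round(size * rate)`` counts and the pool is shuffled.
    """
    rng = random.Random(spec.seed)
    cfg = _default_norm_config()
    n_dup = round(spec.size * spec.duplicate_rate)
    n_twin = round(spec.size * spec.phonetic_twin_rate)
    n_base = spec.size - n_dup - n_twin
    if n_base < 1:
        raise InvalidNameError("rates leave no room for distinct base entries")

    names: list[str] = []
    seen_norm: set[str] = set()
    seen_raw: set[str] = set()
    while len(names) < n_base:
        name = _person_name(rng)
        key = normalize(name, cfg).text
        if key in seen_norm:
            continue
        seen_norm.add(key)
        seen_raw.add(name)
        names.append(name)

    twins: list[str] = []
    while len(twins) < n_twin:
        source = rng.choice(names)
        variant = _phonetic_variant(source, rng)
        if variant in seen_raw:
            continue
        if normalize(variant, cfg).text != normalize(source, cfg).text:
            continue  # mutation crossed a phonetic boundary; retry
        seen_raw.add(variant)
        twins.append(variant)

    combined = names + twins
    duplicates = [rng.choice(combined) for _ in range(n_dup)]
    pool = combined + duplicates
    rng.shuffle(pool)
    return NamePool(names=pool, source="synthetic")


# ---------------------------------------------------------------------------
# Cached per-pool digest tables
# ---------------------------------------------------------------------------


class _PoolCodec:
    """Normalized strings and lazily built digest tables for a pool."""

    def __init__(
        self,
        pool: NamePool,
        sort_enabled: bool = True,
        phonetic_enabled: bool = True,
        salts: tuple[str, ...] = DEFAULT_SALTS,
    ) -> None:
        cfg = _default_norm_config(sort_enabled, phonetic_enabled, salts)
        self.norms = [normalize(name, cfg).text for name in pool.names]
        self.salts = salts
        self._digests: dict = {}

    def digests(self, hash_fn) -> np.ndarray:
        """uint64 digest array under an integer hash type or ``"double"``."""
        arr = self._digests.get(hash_fn)
        if arr is None:
            if hash_fn == "double":
                it = (double_hash(t) for t in self.norms)
            else:
                it = (dispatch_hash(t, hash_fn, self.salts) for t in self.norms)
            arr = np.fromiter(it, dtype=np.uint64, count=len(self.norms))
            self._digests[hash_fn] = arr
        return arr


def _codec(pool: NamePool, config: CodingConfig) -> _PoolCodec:
    key = (config.sort_enabled, config.phonetic_enabled, config.salts)
    codec = pool._codecs.get(key)
    if codec is None:
        codec = _PoolCodec(
            pool, config.sort_enabled, config.phonetic_enabled, config.salts
        )
        pool._codecs[key] = codec
    return codec


def config_for_space(n: int, **kwargs) -> CodingConfig:
    """A CodingConfig whose coding space has exactly ``n`` slots."""
    if n % 10 == 0 and n >= 10:
        return CodingConfig(L=n // 10, coding_factor=10, **kwargs)
    return CodingConfig(L=n, coding_factor=1, **kwargs)


def _derive_seed(*parts: int) -> int:
    """Deterministic per-condition PRNG seed from a base seed and keys."""
    state = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(state.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Integrity experiments
# ---------------------------------------------------------------------------


@dataclass
class IntegrityResult:
    """Aggregated outcome of a collision or encoding-success experiment."""

    k: int
    N: int
    iterations: int
    seed: int
    collision_fraction: float
    collision_fraction_se: float
    success_rate: float
    hash_utilization: dict
    unrecoverable_fraction: float = 0.0
    lookup_mismatch_count: int = 0
    total_adds: int = 0
    all_registries_valid: bool = True

    @property
    def lookup_mismatch_fraction(self) -> float:
        return self.lookup_mismatch_count / self.total_adds if self.total_adds else 0.0


def collision_rate(
    pool: NamePool,
    k: int,
    N: int,
    hash_fn=0,
    iterations: int = 10_000,
    seed: int = 0,
    sort_enabled: bool = True,
    phonetic_enabled: bool = True,
) -> IntegrityResult:
    """Raw collision probability of a single hash function.

    Per iteration, ``k`` names are sampled without replacement, encoded
    with ``hash_fn`` (an integer hash type, or ``"double"`` for the
    half-djb2/half-CRC-32 digest) modulo ``N``, and each item whose ID was
    already produced by an earlier item counts as a collision.  The
    reported ``collision_fraction`` is the mean colliding fraction per
    iteration; on unique uniform names it follows the birthday-occupancy
    law ``1 − N(1−(1−1/N)^k)/k``.
    """
    if k > len(pool):
        raise InvalidNameError(f"sample size {k} exceeds pool size {len(pool)}")
    config = config_for_space(
        N, sort_enabled=sort_enabled, phonetic_enabled=phonetic_enabled
    )
    ids = (_codec(pool, config).digests(hash_fn) % np.uint64(N)).astype(np.int64)
    ids_list = ids.tolist()
    rng = random.Random(_derive_seed(seed, k, N))
    n = len(pool)
    fractions = np.empty(iterations, dtype=np.float64)
    for it in range(iterations):
        idx = rng.sample(range(n), k)
        sampled = [ids_list[i] for i in idx]
        fractions[it] = (k - len(set(sampled))) / k
    mean = float(fractions.mean())
    se = float(fractions.std(ddof=1) / np.sqrt(iterations)) if iterations > 1 else 0.0
    return IntegrityResult(
        k=k,
        N=N,
        iterations=iterations,
        seed=seed,
        collision_fraction=mean,
        collision_fraction_se=se,
        success_rate=float(np.mean(fractions == 0.0)),
        hash_utilization={hash_fn: 1.0},
    )


def encoding_success(
    pool: NamePool,
    k: int,
    N: int,
    iterations: int = 10_000,
    seed: int = 0,
    sort_enabled: bool = True,
    phonetic_enabled: bool = True,
) -> IntegrityResult:
    """Full add-sequence simulation: success rate and hash utilization.

    Per iteration a sample of ``k`` names is registered in order.  A run
    succeeds when no add raises an unrecoverable collision (failed
    participants are recorded and skipped; the rest of the run continues).
    Every successful add is followed by a lookup and compared with the
    assigned ID to measure the validation-code aliasing rate.
    """
    if k > len(pool):
        raise InvalidNameError(f"sample size {k} exceeds pool size {len(pool)}")
    config = config_for_space(
        N, sort_enabled=sort_enabled, phonetic_enabled=phonetic_enabled
    )
    codec = _codec(pool, config)
    n = len(pool)
    np_n = np.uint64(N)
    ids_by_type: dict[int, list[int]] = {}

    def ids_for(hash_type: int) -> list[int]:
        lst = ids_by_type.get(hash_type)
        if lst is None:
            lst = (codec.digests(hash_type) % np_n).astype(np.int64).tolist()
            ids_by_type[hash_type] = lst
        return lst

    ids_for(config.hash_type_default)
    rng = random.Random(_derive_seed(seed, k, N))
    usage: Counter = Counter()
    colliding_fracs = np.empty(iterations, dtype=np.float64)
    failed_runs = 0
    failed_adds = 0
    mismatches = 0
    total_adds = 0
    all_valid = True
    for it in range(iterations):
        idx = rng.sample(range(n), k)
        registry = Registry()
        run_failed = 0
        run_colliding = 0
        assigned: list[tuple[int, int]] = []
        for i in idx:

            def encoder(hash_type: int, i: int = i) -> int:
                return ids_for(hash_type)[i]

            try:
                id_, used_type = _add_encoded(encoder, config, registry)
            except UnrecoverableCollisionError:
                run_failed += 1
                run_colliding += 1
                continue
            usage[used_type] += 1
            if used_type != config.hash_type_default:
                run_colliding += 1
            assigned.append((i, id_))
        for i, id_ in assigned:
            looked_up = _lookup_encoded(
                lambda t, i=i: ids_for(t)[i], config, registry
            )
            if looked_up != id_:
                mismatches += 1
        if len(registry.ids) != len(assigned) or any(
            not 0 <= v < N for v in registry.ids
        ):
            all_valid = False
        total_adds += k
        failed_adds += run_failed
        colliding_fracs[it] = run_colliding / k
        if run_failed:
            failed_runs += 1
    coded = sum(usage.values())
    return IntegrityResult(
        k=k,
        N=N,
        iterations=iterations,
        seed=seed,
        collision_fraction=float(colliding_fracs.mean()),
        collision_fraction_se=float(
            colliding_fracs.std(ddof=1) / np.sqrt(iterations)
        )
        if iterations > 1
        else 0.0,
        success_rate=1.0 - failed_runs / iterations,
        hash_utilization={t: c / coded for t, c in sorted(usage.items())},
        unrecoverable_fraction=failed_adds / total_adds,
        lookup_mismatch_count=mismatches,
        total_adds=total_adds,
        all_registries_valid=all_valid,
    )


def build_registry(
    pool: NamePool,
    k: int,
    N: int,
    seed: int = 0,
    max_attempts: int = 100,
    sort_enabled: bool = True,
    phonetic_enabled: bool = True,
) -> tuple[CodingConfig, Registry, list[int]]:
    """One successful encoding of ``k`` pool names into a space of ``N``.

    Samples are redrawn (up to ``max_attempts``) until every add succeeds,
    mirroring how an evaluation selects a successful encoding per
    condition.  Returns the configuration, the registry and the indices of
    the registered pool names.
    """
    config = config_for_space(
        N, sort_enabled=sort_enabled, phonetic_enabled=phonetic_enabled
    )
    codec = _codec(pool, config)
    np_n = np.uint64(N)
    ids_by_type: dict[int, list[int]] = {}

    def ids_for(hash_type: int) -> list[int]:
        lst = ids_by_type.get(hash_type)
        if lst is None:
            lst = (codec.digests(hash_type) % np_n).astype(np.int64).tolist()
            ids_by_type[hash_type] = lst
        return lst

    rng = random.Random(_derive_seed(seed, k, N, 7))
    for _ in range(max_attempts):
        idx = rng.sample(range(len(pool)), k)
        registry = Registry()
        try:
            for i in idx:
                _add_encoded(lambda t, i=i: ids_for(t)[i], config, registry)
        except UnrecoverableCollisionError:
            continue
        return config, registry, idx
    raise UnrecoverableCollisionError(
        f"no fully successful encoding found in {max_attempts} attempts "
        f"(k={k}, N={N})"
    )


# ---------------------------------------------------------------------------
# Anonymity: phonebook attack
# ---------------------------------------------------------------------------


@dataclass
class AnonymityReport:
    """Outcome of a phonebook attack on one encoding."""

    N: int
    pool_size: int
    hits_per_slot: np.ndarray
    min_hits: int
    mean_hits: float
    max_hits: int
    mean_hits_per_space_slot: float
    rejectable_fraction: float
    unused_slot_fraction: float

    @property
    def k_anonymity(self) -> int:
        """Minimum phonebook hits over assigned IDs."""
        return self.min_hits


def phonebook_attack(
    config: CodingConfig, registry: Registry, pool: NamePool
) -> AnonymityReport:
    """Attack an encoding with a candidate name list.

    The attacker is assumed to hold the full state file — assigned IDs and
    attachment tables — so every pool name is resolved with the complete
    lookup semantics (validation codes included).  Hits per slot are
    tallied; names resolving to unassigned IDs are *rejectable* (provably
    non-participants), and the minimum hit count over assigned IDs is the
    k-anonymity of the encoding.
    """
    if not registry.ids:
        raise InvalidNameError("registry is empty; nothing to attack")
    n = config.N
    codec = _codec(pool, config)
    ids0 = (codec.digests(config.hash_type_default) % np.uint64(n)).astype(np.int64)
    final = ids0.copy()
    attach_keys = [id_ for id_, entries in registry.attachments.items() if entries]
    if attach_keys:
        affected = np.nonzero(np.isin(ids0, attach_keys))[0]
        for i in affected:

            def encoder(hash_type: int, i: int = int(i)) -> int:
                return int(codec.digests(hash_type)[i] % np.uint64(n))

            final[i] = _lookup_encoded(encoder, config, registry)
    hits = np.bincount(final, minlength=n)
    assigned = np.fromiter(registry.ids, dtype=np.int64, count=len(registry.ids))
    hits_assigned = hits[assigned]
    pool_size = len(pool)
    return AnonymityReport(
        N=n,
        pool_size=pool_size,
        hits_per_slot=hits,
        min_hits=int(hits_assigned.min()),
        mean_hits=float(hits_assigned.mean()),
        max_hits=int(hits_assigned.max()),
        mean_hits_per_space_slot=pool_size / n,
        rejectable_fraction=1.0 - float(hits_assigned.sum()) / pool_size,
        unused_slot_fraction=float((hits == 0).sum()) / n,
    )


# ---------------------------------------------------------------------------
# Condition sweeps
# ---------------------------------------------------------------------------


def sweep(
    ks: Sequence[int],
    Ns: Sequence[int],
    pool: NamePool,
    iterations: int = 10_000,
    seed: int = 0,
    run_success: bool = True,
    run_attack: bool = False,
    output: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Run experiments over a ``k × N`` grid and return a tidy table.

    One row per condition per metric, with the condition keys
    (k, N, iterations, seed, pool source) as columns.  When ``output`` is
    given the table is also written as CSV.  An empty grid yields an empty
    table.
    """
    rows: list[dict] = []
    for N in Ns:
        for k in ks:
            base = {
                "k": k,
                "N": N,
                "iterations": iterations,
                "seed": seed,
                "pool_source": pool.source,
            }
            if run_success:
                res = encoding_success(pool, k, N, iterations=iterations, seed=seed)
                metrics = {
                    "success_rate": res.success_rate,
                    "collision_fraction": res.collision_fraction,
                    "unrecoverable_fraction": res.unrecoverable_fraction,
                    "lookup_mismatch_fraction": res.lookup_mismatch_fraction,
                }
                for t, freq in res.hash_utilization.items():
                    metrics[f"hash_utilization[{t}]"] = freq
                rows.extend({**base, "metric": m, "value": v} for m, v in metrics.items())
            if run_attack:
                config, registry, _ = build_registry(pool, k, N, seed=seed)
                rep = phonebook_attack(config, registry, pool)
                metrics = {
                    "k_anonymity": float(rep.k_anonymity),
                    "min_hits": float(rep.min_hits),
                    "mean_hits": rep.mean_hits,
                    "max_hits": float(rep.max_hits),
                    "mean_hits_per_space_slot": rep.mean_hits_per_space_slot,
                    "rejectable_fraction": rep.rejectable_fraction,
                    "unused_slot_fraction": rep.unused_slot_fraction,
                }
                rows.extend({**base, "metric": m, "value": v} for m, v in metrics.items())
    columns = ["k", "N", "iterations", "seed", "pool_source", "metric", "value"]
    table = pd.DataFrame(rows, columns=columns)
    if output is not None:
        table.to_csv(output, index=False)
    return table
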