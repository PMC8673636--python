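"""Stateful core: adding participants, resolving collisions, looking up IDs.

The study state is an *ID list* — the set of assigned IDs — plus, for each
ID at which a collision occurred, an ordered list of attachments.  An
attachment records which alternative hash type resolved the collision and a
*validation code* (a second truncated hash computed with the hash type
shifted by a fixed offset of 10) that lets a later lookup recognise which
name the attachment belongs to.  No names are ever stored: the state file
can be kept openly without acting as a linking table.

Adding a participant
    Encode with the default hash (type 0).  If the ID is free, assign it.
    Otherwise search hash types 1, 2, ... for the first whose ID is free
    and whose validation type (index + 10) is computable, attach
    ``(hash_type, validation_code)`` to the *original* colliding ID, and
    assign the alternative ID.  If no computable hash type yields a free
    ID the collision is unrecoverable.

Looking up a participant
    Encode with the default hash.  Walk that ID's attachments in insertion
    order; the first whose stored validation code matches the name's own
    validation code under that hash type redirects to the alternative ID.
    With no match, the default ID stands.  A name that was never added
    still returns *some* ID — detecting that misuse is the researcher's
    responsibility, as is never adding the same participant twice.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass
from typing import Callable

from .errors import (
    ConfigError,
    CorruptStateError,
    UncomputableHashError,
    UnrecoverableCollisionError,
)
from .hashing import DEFAULT_SALTS, dispatch_hash, max_hash_type, truncate_digest
from .normalization import normalize

__all__ = [
    "AnonymityAdvisory",
    "AttachmentEntry",
    "CodingConfig",
    "Registry",
    "Study",
    "add",
    "deserialize_state",
    "encode",
    "find_free_slot",
    "lookup",
    "population_advisory",
    "serialize_state",
    "validation_code",
]

STATE_FORMAT = "candidate-state"
STATE_VERSION = 1

#: Recommended k-anonymity floor for recruiting populations.
RECOMMENDED_K_ANONYMITY = 5


@dataclass(frozen=True)
class CodingConfig:
    """Study-level coding parameters.

    Parameters
    ----------
    L
        Maximum anticipated number of participants.
    coding_factor
        Ratio of coding-space size to ``L``; 10 is the recommended
        compromise between integrity (few unresolvable collisions) and
        anonymity (many population names per ID).
    sort_enabled, phonetic_enabled
        Switches for the two optional normalization steps.
    salts
        Ordered salt table for hash types 9 and up.
    hash_type_offset
        Offset added to a hash type to derive its validation-code type.
    """

    L: int
    coding_factor: int = 10
    sort_enabled: bool = True
    phonetic_enabled: bool = True
    salts: tuple[str, ...] = DEFAULT_SALTS
    hash_type_default: int = 0
    hash_type_offset: int = 10

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ConfigError(f"L must be >= 1, got {self.L}")
        if self.coding_factor < 1:
            raise ConfigError(f"coding_factor must be >= 1, got {self.coding_factor}")
        if self.hash_type_offset < 1:
            raise ConfigError("hash_type_offset must be >= 1")
        object.__setattr__(self, "salts", tuple(self.salts))

    @property
    def N(self) -> int:
        """Coding-space size: ``coding_factor × L``."""
        return self.coding_factor * self.L

    @property
    def max_hash_type(self) -> int:
        return max_hash_type(self.salts)

    @property
    def id_width(self) -> int:
        """Digit width of the largest ID, for zero-padded display."""
        return len(str(self.N - 1))

    def format_id(self, id_: int) -> str:
        return f"{id_:0{self.id_width}d}"


@dataclass(frozen=True)
class AttachmentEntry:
    """Collision-resolution record attached to an occupied ID."""

    hash_type: int
    validation_code: int


class Registry:
    """The persisted ID list with per-ID attachment lists."""

    def __init__(self) -> None:
        self.ids: set[int] = set()
        self.attachments: dict[int, list[AttachmentEntry]] = {}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, id_: int) -> bool:
        return id_ in self.ids

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return self.ids == other.ids and self.attachments == other.attachments

    def assign(self, id_: int) -> None:
        if id_ in self.ids:
            raise ValueError(f"ID {id_} already assigned")
        self.ids.add(id_)

    def attach(self, id_: int, entry: AttachmentEntry) -> None:
        if id_ not in self.ids:
            raise ValueError(f"cannot attach to unassigned ID {id_}")
        self.attachments.setdefault(id_, []).append(entry)

    def attachments_for(self, id_: int) -> list[AttachmentEntry]:
        return self.attachments.get(id_, [])

    def copy(self) -> "Registry":
        new = Registry()
        new.ids = set(self.ids)
        new.attachments = {k: list(v) for k, v in self.attachments.items()}
        return new


@dataclass(frozen=True)
class AnonymityAdvisory:
    """Population-size advisory for a target k-anonymity."""

    k_min: int
    L: int

    @property
    def required_population(self) -> int:
        return self.k_min * self.L


def population_advisory(k_min: int, L: int) -> AnonymityAdvisory:
    """Minimum recruiting-population size for k-anonymity: ``k_min × L``.

    Every name in the population that truncates onto an assigned ID is an
    alias for that participant under a phonebook attack; recruiting from a
    population of at least ``k_min × L`` is required for each assigned ID
    to plausibly attract ``k_min`` aliases.
    """
    if k_min < 1 or L < 1:
        raise ConfigError("k_min and L must be >= 1")
    return AnonymityAdvisory(k_min=k_min, L=L)


# ---------------------------------------------------------------------------
# Encoding and the encoder-closure core.
#
# The public operations take a raw name; the *_encoded variants take a
# closure hash_type -> ID so that simulations can drive the identical
# algorithm from precomputed digest tables without re-normalizing.
# ---------------------------------------------------------------------------

Encoder = Callable[[int], int]


def _encoder_for(name: str, config: CodingConfig) -> Encoder:
    text = normalize(name, config).text
    n = config.N
    salts = config.salts

    def encoder(hash_type: int) -> int:
        return truncate_digest(dispatch_hash(text, hash_type, salts), n)

    return encoder


def encode(name: str, config: CodingConfig, hash_type: int | None = None) -> int:
    """Truncated hash of the normalized name: ``Hash(name) mod N``."""
    if hash_type is None:
        hash_type = config.hash_type_default
    return _encoder_for(name, config)(hash_type)


def _find_free_slot_encoded(
    encoder: Encoder, config: CodingConfig, registry: Registry
) -> int:
    offset = config.hash_type_offset
    top = config.max_hash_type
    for hash_type in range(1, top + 1):
        if hash_type + offset > top:
            # A validation code could not be attached for this type.
            continue
        if encoder(hash_type) not in registry:
            return hash_type
    raise UnrecoverableCollisionError(
        "no computable hash type maps the name to a free ID"
    )


def _add_encoded(
    encoder: Encoder, config: CodingConfig, registry: Registry
) -> tuple[int, int]:
    """Add via an encoder closure; returns ``(assigned_id, hash_type_used)``."""
    id_original = encoder(config.hash_type_default)
    if id_original not in registry:
        registry.assign(id_original)
        return id_original, config.hash_type_default
    free_type = _find_free_slot_encoded(encoder, config, registry)
    try:
        vcode = encoder(free_type + config.hash_type_offset)
    except UncomputableHashError as exc:  # guarded above; defensive
        raise UnrecoverableCollisionError(str(exc)) from exc
    id_alternative = encoder(free_type)
    registry.attach(id_original, AttachmentEntry(free_type, vcode))
    registry.assign(id_alternative)
    return id_alternative, free_type


def _lookup_encoded(encoder: Encoder, config: CodingConfig, registry: Registry) -> int:
    id_original = encoder(config.hash_type_default)
    for entry in registry.attachments_for(id_original):
        contender_validation = encoder(entry.hash_type + config.hash_type_offset)
        if contender_validation == entry.validation_code:
            return encoder(entry.hash_type)
    return id_original


def add(name: str, config: CodingConfig, registry: Registry) -> int:
    """Register a new participant and return their assigned ID.

    The registry is mutated in place.  Raises
    :class:`UnrecoverableCollisionError` (leaving the registry unchanged)
    when every available hash type collides.  Adding the same name twice is
    NOT detected — by design the tool stores no names, so knowing whether a
    participant is new rests with the researcher.
    """
    encoder = _encoder_for(name, config)
    snapshot = registry.copy()
    try:
        assigned, _ = _add_encoded(encoder, config, registry)
    except UnrecoverableCollisionError:
        registry.ids = snapshot.ids
        registry.attachments = snapshot.attachments
        raise
    return assigned


def find_free_slot(name: str, config: CodingConfig, registry: Registry) -> int:
    """Smallest alternative hash type mapping ``name`` to a free ID."""
    return _find_free_slot_encoded(_encoder_for(name, config), config, registry)


def validation_code(name: str, config: CodingConfig, free_type: int) -> int:
    """Validation code: encode with hash type ``free_type + offset``."""
    try:
        return encode(name, config, free_type + config.hash_type_offset)
    except UncomputableHashError as exc:
        raise UnrecoverableCollisionError(str(exc)) from exc


def lookup(name: str, config: CodingConfig, registry: Registry) -> int:
    """ID of a previously added participant.

    A name that was never added silently returns an ID as well (it cannot
    be distinguished without storing names); callers can at least check
    membership of the result in ``registry.ids``.
    """
    return _lookup_encoded(_encoder_for(name, config), config, registry)


# ---------------------------------------------------------------------------
# State persistence
# ---------------------------------------------------------------------------


def serialize_state(config: CodingConfig, registry: Registry) -> dict:
    """Canonical JSON-ready document for the study state.

    IDs are emitted in ascending numeric order; attachment lists keep
    insertion order (it is semantically meaningful at lookup).
    """
    return {
        "format": STATE_FORMAT,
        "version": STATE_VERSION,
        "config": {
            "L": config.L,
            "codingFactor": config.coding_factor,
            "N": config.N,
            "sortEnabled": config.sort_enabled,
            "phoneticEnabled": config.phonetic_enabled,
            "salts": list(config.salts),
            "hashTypeOffset": config.hash_type_offset,
        },
        "ids": [
            {
                "id": id_,
                "attachments": [
                    {"hashType": e.hash_type, "validationCode": e.validation_code}
                    for e in registry.attachments_for(id_)
                ],
            }
            for id_ in sorted(registry.ids)
        ],
    }


def state_to_json(config: CodingConfig, registry: Registry) -> str:
    return json.dumps(serialize_state(config, registry), indent=1) + "\n"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise CorruptStateError(msg)


def deserialize_state(document: dict | str) -> tuple[CodingConfig, Registry]:
    """Reconstruct ``(config, registry)`` from a state document.

    Accepts the parsed dict or its JSON text.  All registry invariants are
    re-checked; any violation raises :class:`CorruptStateError`.
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as exc:
            raise CorruptStateError(f"state file is not valid JSON: {exc}") from exc
    _require(isinstance(document, dict), "state document must be a JSON object")
    _require(document.get("format") == STATE_FORMAT, "unrecognised state format tag")
    _require(document.get("version") == STATE_VERSION, "unsupported state version")

    cfg = document.get("config")
    _require(isinstance(cfg, dict), "missing config object")
    for key, typ in (
        ("L", int), ("codingFactor", int), ("N", int),
        ("sortEnabled", bool), ("phoneticEnabled", bool),
        ("hashTypeOffset", int),
    ):
        _require(isinstance(cfg.get(key), typ) and not (
            typ is int and isinstance(cfg.get(key), bool)
        ), f"config field {key!r} missing or of wrong type")
    salts = cfg.get("salts")
    _require(
        isinstance(salts, list) and all(isinstance(s, str) for s in salts),
        "config field 'salts' must be a list of strings",
    )
    try:
        config = CodingConfig(
            L=cfg["L"],
            coding_factor=cfg["codingFactor"],
            sort_enabled=cfg["sortEnabled"],
            phonetic_enabled=cfg["phoneticEnabled"],
            salts=tuple(salts),
            hash_type_offset=cfg["hashTypeOffset"],
        )
    except ConfigError as exc:
        raise CorruptStateError(str(exc)) from exc
    _require(config.N == cfg["N"], "config field N != codingFactor * L")

    entries = document.get("ids")
    _require(isinstance(entries, list), "missing ids list")
    registry = Registry()
    for item in entries:
        _require(isinstance(item, dict), "ids entries must be objects")
        id_ = item.get("id")
        _require(
            isinstance(id_, int) and not isinstance(id_, bool), "id must be an integer"
        )
        _require(0 <= id_ < config.N, f"ID {id_} outside [0, {config.N})")
        _require(id_ not in registry.ids, f"duplicate ID {id_}")
        registry.ids.add(id_)
        attachments = item.get("attachments", [])
        _require(isinstance(attachments, list), "attachments must be a list")
        for att in attachments:
            _require(isinstance(att, dict), "attachment entries must be objects")
            ht, vc = att.get("hashType"), att.get("validationCode")
            _require(
                isinstance(ht, int) and not isinstance(ht, bool),
                "hashType must be an integer",
            )
            _require(
                isinstance(vc, int) and not isinstance(vc, bool),
                "validationCode must be an integer",
            )
            _require(
                config.hash_type_default < ht
                and ht + config.hash_type_offset <= config.max_hash_type,
                f"hashType {ht} not a usable alternative hash type",
            )
            _require(0 <= vc < config.N, f"validationCode {vc} outside [0, {config.N})")
            registry.attach(id_, AttachmentEntry(ht, vc))
    return config, registry


class Study:
    """Convenience wrapper binding a configuration and a registry.

    Provides the researcher-facing operations and atomic file persistence;
    the module-level functions remain the primitive API.
    """

    def __init__(self, config: CodingConfig, registry: Registry | None = None) -> None:
        self.config = config
        self.registry = registry if registry is not None else Registry()

    @classmethod
    def create(cls, L: int, coding_factor: int = 10, **kwargs) -> "Study":
        return cls(CodingConfig(L=L, coding_factor=coding_factor, **kwargs))

    def add(self, name: str) -> int:
        return add(name, self.config, self.registry)

    def lookup(self, name: str) -> int:
        return lookup(name, self.config, self.registry)

    def advisory(self, k_min: int = RECOMMENDED_K_ANONYMITY) -> AnonymityAdvisory:
        return population_advisory(k_min, self.config.L)

    def format_id(self, id_: int) -> str:
        return self.config.format_id(id_)

    def to_json(self) -> str:
        return state_to_json(self.config, self.registry)

    def save(self, path: str | os.PathLike) -> None:
        """Atomically rewrite the state file (write-temp + rename)."""
        path = os.fspath(path)
        directory = os.path.dirname(os.path.abspath(path))
        fd, tmp = tempfile.mkstemp(prefix=".pseudoid-", dir=directory, text=True)
        try:
            with os.fdopen(fd, "w", encoding="utf-8") as fh:
                fh.write(self.to_json())
            os.replace(tmp, path)
        except BaseException:
            try:
                os.unlink(tmp)
            except OSError:
                pass
            raise

    @classmethod
    def load(cls, path: str | os.PathLike) -> "Study":
        with open(path, "r", encoding="utf-8") as fh:
            config, registry = deserialize_state(fh.read())
        return cls(config, registry)
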