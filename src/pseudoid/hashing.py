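"""The 32-bit hash family used to map names onto the coding space.

Two base algorithms are used: djb2 (Bernstein's multiply-by-33 string hash)
and CRC-32.  From these a family of variants is derived — the reversed
input, the input rotated by 1-5 positions, and the input concatenated with
each of a fixed salt table — giving one independent-looking hash function
per *hash type* index:

====  =================================
type  digest
====  =================================
0     djb2(s)                 (default)
1     crc32(s)
2     crc32(reverse(s))
3     djb2(reverse(s))
4-8   djb2(rotate(s, 1..5))
9-18  djb2(s + salt[type - 9])
====  =================================

Indices beyond ``8 + len(salts)`` are uncomputable and raise
:class:`~pseudoid.errors.UncomputableHashError`.  Truncation of a digest to
an ID is plain ``digest mod N`` where ``N`` is the coding-space size; the
truncation is deliberately lossy — many names share each ID, which is what
provides anonymity.
"""

from __future__ import annotations

import zlib

from .errors import ConfigError, InvalidNameError, UncomputableHashError

__all__ = [
    "DEFAULT_SALTS",
    "DJB2_SEED",
    "crc32",
    "dispatch_hash",
    "djb2",
    "double_hash",
    "max_hash_type",
    "rotate",
    "truncate_digest",
]

_U32 = 0xFFFFFFFF

#: Initial accumulator of the djb2 recurrence.
DJB2_SEED = 5381

#: Frozen salt table: the ten most frequent English words, lowercase, in
#: frequency order.  Salted hash types are 9 .. 8 + len(DEFAULT_SALTS).
DEFAULT_SALTS: tuple[str, ...] = (
    "the", "be", "to", "of", "and", "a", "in", "that", "have", "i",
)

#: Number of non-salted hash types (indices 0-8).
_FIXED_TYPES = 9


def _ascii(text: str) -> bytes:
    try:
        return text.encode("ascii")
    except UnicodeEncodeError as exc:
        raise InvalidNameError(
            f"hash input must be ASCII after normalization: {text!r}"
        ) from exc


def djb2(text: str) -> int:
    """Bernstein's string hash: start at 5381, then ``h = h*33 + char``.

    Arithmetic is unsigned 32-bit with wraparound, matching the width of
    CRC-32 and the common reference implementation.
    """
    h = DJB2_SEED
    for b in _ascii(text):
        h = (h * 33 + b) & _U32
    return h


def crc32(text: str) -> int:
    """Standard reflected CRC-32 (poly 0xEDB88320, init/final 0xFFFFFFFF)."""
    return zlib.crc32(_ascii(text)) & _U32


def rotate(text: str, k: int) -> str:
    """Left circular rotation of the character sequence by ``k`` positions."""
    if not text:
        return text
    k %= len(text)
    return text[k:] + text[:k]


def max_hash_type(salts: tuple[str, ...] = DEFAULT_SALTS) -> int:
    """Largest computable hash-type index: ``8 + number of salts``."""
    return _FIXED_TYPES - 1 + len(salts)


def dispatch_hash(
    text: str, hash_type: int, salts: tuple[str, ...] = DEFAULT_SALTS
) -> int:
    """Digest of ``text`` under the family member ``hash_type``.

    Raises
    ------
    UncomputableHashError
        If ``hash_type`` is negative or beyond ``8 + len(salts)`` — the
        "cannot compute hash" condition that makes a collision
        unrecoverable when reached during slot search.
    """
    if hash_type == 0:
        return djb2(text)
    if hash_type == 1:
        return crc32(text)
    if hash_type == 2:
        return crc32(text[::-1])
    if hash_type == 3:
        return djb2(text[::-1])
    if 4 <= hash_type <= 8:
        return djb2(rotate(text, hash_type - 3))
    if _FIXED_TYPES <= hash_type <= max_hash_type(salts):
        return djb2(text + salts[hash_type - _FIXED_TYPES])
    raise UncomputableHashError(f"cannot compute hash type {hash_type}")


def truncate_digest(digest: int, n: int) -> int:
    """Truncate a 32-bit digest to an ID in ``[0, n)`` by taking it mod n."""
    if n <= 0:
        raise ConfigError(f"coding-space size must be >= 1, got {n}")
    return digest % n


def double_hash(text: str) -> int:
    """32-bit digest combining djb2 (upper 16 bits) and CRC-32 (lower 16).

    Used only in collision-rate benchmarking of the raw hash primitives;
    it is not a member of the hash-type family above.
    """
    return ((djb2(text) & 0xFFFF) << 16) | (crc32(text) & 0xFFFF)
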