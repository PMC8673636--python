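"""Name normalization: sanitation, token sorting, full-length Soundex.

A participant is represented by their full name in Latin characters.  Before
hashing, the name is normalized to absorb common input variations:

1. *Sanitation* removes punctuation (hyphens, apostrophes, periods, ...)
   and collapses whitespace, so "Anne-Marie O'Neil" and "AnneMarie ONeil"
   code identically.
2. *Sorting* orders the name parts alphabetically, so "Rodman David M" and
   "David M Rodman" code identically.
3. *Phonetic coding* replaces each name part by its full-length Soundex
   code, absorbing vowel changes, doubled consonants and similar-sounding
   consonant substitutions.  Unlike classic Soundex, the code is NOT
   truncated to four characters: "Christian" becomes C6235, not C623.

The sorting and phonetic steps can each be switched off; when both are off
the raw input passes through byte-for-byte (useful for non-name
representations such as phone numbers, where the error-tolerance mechanisms
do not apply).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING

from .errors import InvalidNameError

if TYPE_CHECKING:  # pragma: no cover
    from .linker import CodingConfig

__all__ = [
    "NormalizedName",
    "normalize",
    "sanitize",
    "sort_name_parts",
    "soundex_full",
    "stripped_characters",
]

# Consonant classes of the Soundex algorithm.
_SOUNDEX_CLASS = {}
for _letters, _digit in (
    ("BFPV", "1"),
    ("CGJKQSXZ", "2"),
    ("DT", "3"),
    ("L", "4"),
    ("MN", "5"),
    ("R", "6"),
):
    for _ch in _letters:
        _SOUNDEX_CLASS[_ch] = _digit

_KEEP = re.compile(r"[A-Za-z0-9 ]")
_ASCII_LETTER = re.compile(r"[A-Za-z]")


@dataclass(frozen=True)
class NormalizedName:
    """The canonical form of a name that is actually hashed.

    Attributes
    ----------
    text
        The string fed to the hash functions.
    parts
        The per-token pieces of ``text`` (phonetic codes when the phonetic
        step is on, sanitized tokens otherwise, or the raw input as a
        single part when normalization is fully disabled).
    """

    text: str
    parts: tuple[str, ...]


def _check_raw(raw: str) -> str:
    if not isinstance(raw, str):
        raise InvalidNameError(f"name must be a string, got {type(raw).__name__}")
    if not raw.strip():
        raise InvalidNameError("name is empty")
    if not _ASCII_LETTER.search(raw):
        raise InvalidNameError(f"name contains no Latin letter: {raw!r}")
    return raw


def stripped_characters(raw: str) -> list[str]:
    """Characters of ``raw`` that :func:`sanitize` would remove, in order.

    Used by the command-line interface to warn about invalid input
    characters without silently altering what the researcher typed.
    """
    return [ch for ch in raw if not _KEEP.fullmatch(ch) and not ch.isspace()]


def sanitize(raw: str) -> str:
    """Strip unwanted characters and collapse whitespace.

    Only Latin letters, digits and single-space separators survive; hyphens,
    apostrophes, periods, commas and every other character are removed.
    Raises :class:`InvalidNameError` if nothing remains.
    """
    _check_raw(raw)
    kept = []
    for ch in raw:
        if _KEEP.fullmatch(ch):
            kept.append(ch)
        elif ch.isspace():
            kept.append(" ")
        # every other character is dropped
    clean = " ".join("".join(kept).split())
    if not clean:
        raise InvalidNameError(f"name is empty after sanitation: {raw!r}")
    return clean


def sort_name_parts(clean: str) -> str:
    """Sort space-separated name parts into alphabetical order.

    Comparison is case-insensitive (casefolded), with the exact spelling as
    a tie-break so the result is invariant under any permutation of the
    input tokens.
    """
    tokens = clean.split(" ")
    tokens.sort(key=lambda t: (t.casefold(), t))
    return " ".join(tokens)


def soundex_full(token: str) -> str:
    """Full-length Soundex code of a single name part.

    The first letter is kept (uppercased); each following letter maps to
    its consonant class (b f p v -> 1; c g j k q s x z -> 2; d t -> 3;
    l -> 4; m n -> 5; r -> 6).  Vowels and y are dropped but separate
    repeated class digits; h and w are dropped and do NOT separate them;
    runs of the same class collapse to a single digit.  No truncation to
    four characters is applied.
    """
    if not token or not token.isascii() or not token.isalpha():
        raise InvalidNameError(
            f"phonetic coding requires a token of Latin letters: {token!r}"
        )
    upper = token.upper()
    first = upper[0]
    out = [first]
    prev = _SOUNDEX_CLASS.get(first)  # first letter's class suppresses an
    for ch in upper[1:]:              # immediately repeated class digit
        if ch in "HW":
            continue
        digit = _SOUNDEX_CLASS.get(ch)
        if digit is None:  # vowel or Y: emits nothing but resets the run
            prev = None
            continue
        if digit != prev:
            out.append(digit)
        prev = digit
    return "".join(out)


def normalize(raw: str, config: "CodingConfig") -> NormalizedName:
    """Apply the configured normalization pipeline to a raw name.

    With both sorting and phonetic coding disabled the raw text passes
    through verbatim (sanitation included in neither), reproducing the
    behavior needed for non-name representations.  Otherwise the name is
    sanitized, optionally sorted, and optionally coded phonetically; the
    phonetic codes are concatenated with no separator.
    """
    _check_raw(raw)
    if not config.sort_enabled and not config.phonetic_enabled:
        return NormalizedName(text=raw, parts=(raw,))
    clean = sanitize(raw)
    if config.sort_enabled:
        clean = sort_name_parts(clean)
    tokens = tuple(clean.split(" "))
    if not config.phonetic_enabled:
        return NormalizedName(text=clean, parts=tokens)
    if any(not t.isalpha() for t in tokens):
        raise InvalidNameError(
            "phonetic coding supports letters only; disable the phonetic "
            f"step for digit-bearing representations: {raw!r}"
        )
    codes = tuple(soundex_full(t) for t in tokens)
    return NormalizedName(text="".join(codes), parts=codes)
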