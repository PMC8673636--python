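# Methods

## Model

A participant's ID is a truncated hash of their normalized name:
`ID = H_t(norm(name)) mod N`, where `N = c·L` is the coding-space size for
`L` anticipated participants and coding factor `c` (default 10), and
`H_t` is member `t` of a 19-member hash family. The scheme rests on three
assumptions: (a) the set of assigned IDs is known (it is the persisted
state), (b) the researcher knows whether they are adding a new participant
or looking one up — duplicate adds are *not* detectable, because no names
are stored — and (c) each participant's name is entered consistently
(a sometimes-omitted middle name defeats linking; only spelling-level
variation is absorbed).

### Normalization

Sanitation keeps Latin letters, digits and single spaces and drops
everything else; name parts are then sorted case-insensitively (exact
spelling as tie-break, so the result is strictly permutation-invariant);
finally each part is replaced by its full-length Soundex code and the
codes are concatenated without separator. Soundex here follows the
classic consonant classes (b f p v→1, c g j k q s x z→2, d t→3, l→4,
m n→5, r→6) with h/w transparent inside a run and vowels/y acting as run
separators, but without the classic truncation to four characters.
Sorting and phonetic coding can each be disabled; with both disabled the
raw string passes through byte-for-byte (the mode for non-name
representations such as phone numbers, where phonetic tolerance is
meaningless and digits must survive). Phonetic mode refuses digit-bearing
tokens outright rather than coding them partially.

### Hash family

Type 0 is djb2 (h ← h·33 + char, unsigned 32-bit); type 1 CRC-32
(reflected, polynomial 0xEDB88320); types 2/3 the two base hashes on the
reversed string; types 4–8 djb2 of the string rotated left by 1–5; types
9–18 djb2 of the string concatenated with a fixed salt table (the ten
most frequent English words in frequency order: the, be, to, of, and, a,
in, that, have, i). Indices beyond 18 are uncomputable. Validation codes
use the colliding participant's free type shifted by the constant offset
10, so alternative types are only usable up to 8 (9–18 would need
validation types beyond the family and are skipped by the slot search);
in practice utilization beyond type 3 is already below 10⁻⁴ at `N = 10·L`.

The family is *not* a set of independent uniform hashes. Because
33 ≡ 1 (mod 8), every djb2 digest is congruent to 5381 + Σ(chars) mod 8;
all djb2-of-permuted-input variants therefore agree mod 8 (pairwise
collision rate 8/N at N = 1000 rather than 1/N), equal-length salts
induce a constant digest difference (pairwise rate exactly 0 or 1), and
differing salt sums mod 8 make collisions impossible. None of this harms
the algorithm — the slot search only needs *some* member to yield a free
slot, and measured utilization and success rates match the
independent-hash prediction to four decimals — but the structure is real
and the test suite asserts it rather than the idealized 1/N.

### Collision handling and lookup

`add` assigns the type-0 ID when free; otherwise the lowest alternative
type with a free slot wins, the pair (type, validation code) is appended
to the *original* colliding ID (multiple colliders accumulate in
insertion order), and the alternative ID is assigned. `lookup` walks the
attachments of the name's type-0 ID in order and redirects on the first
validation-code match, else returns the type-0 ID.

Two hazards are measured rather than prevented, faithful to the scheme:

- **Validation aliasing.** Two attachments (or an owner and an
  attachment) can share a validation value with probability ≈ 1/N per
  attachment, sending a lookup to the wrong ID. At `k = 100`, `N = 1000`
  the measured rate is ≈ 4 × 10⁻⁴ per add (10⁶ simulated adds).
- **Duplicate adds.** Re-adding a name is an ordinary collision: the
  duplicate receives a second, distinct ID, and because its validation
  code derives from the same name it *redirects the original's lookups*.
  Assumption (b) places avoiding this on the researcher.

The population advisory printed at study creation is `k_min × L` with the
recommended floor `k_min = 5`. (One published description of this
advisory quotes a population of 500 for `L = 20`, which its own formula
contradicts — `5 × 20 = 100`; the formula is implemented as stated.)

## Persistence

The state is a versioned JSON document (`"format": "candidate-state"`)
holding the coding parameters, the sorted ID list and each ID's
attachment list in insertion order. Deserialization re-validates every
invariant (types, ranges, uniqueness, usable hash types) and rejects
anything else as corrupt. CLI writes are atomic (temp file + rename), so
a failed add never damages an existing state file. IDs are displayed
zero-padded to the digit width of `N − 1` but stored as integers.

## Simulation design

Sampling is without replacement within an iteration; per-condition PRNG
streams are derived from the user seed and the condition keys (k, N)
through `numpy`'s `SeedSequence`, so any condition is reproducible in
isolation. "Collision probability" is operationalized as the expected
fraction of items whose ID was already occupied at insertion — the
quantity that equals `1 − N(1−(1−1/N)^k)/k` for unique uniform names.
A run of `encoding_success` counts as successful when no add raised an
unrecoverable collision; a failed participant is recorded and the run
continues, keeping per-add statistics well-defined. Phonebook attacks use
the complete lookup semantics (the attacker holds the state file,
validation codes included); hits are conserved — every pool name resolves
to exactly one ID — so the mean hits per space slot is identically
`pool size / N`.

Default problem sizes mirror the evaluation design this harness
implements: a phonebook of 103,472 names, sample sizes 10–100 (step 10)
and 100–1,000 (step 100), coding spaces 100–100,000, and 10,000
iterations per condition; the bundled tests run the 10,000-iteration
conditions at `k = 100` and the full-size phonebook.

### Synthetic name pools

The generator emulates a phonebook of unique multi-part person names:
"Given [Middle] Family" built from a syllable model (onset–vowel–coda),
with middle parts as initials or short names for half the entries. Base
entries are rejection-sampled until pairwise distinct *after the full
default normalization* — distinctness after Soundex being the property
that matters for collision behavior. Controlled imperfections can be
injected: `duplicate_rate` inserts exact copies, `phonetic_twin_rate`
inserts differently spelled but phonetically identical variants (vowel
swaps, within-class consonant swaps, consonant doubling, trailing
vowels), each at exactly `round(size × rate)` entries.

What the synthetic pool does **not** emulate: the name-frequency skew,
initial-only entries and — above all — the phonetically duplicate names
of a real 103,472-entry researcher-name list. On that list, single-hash
collision rates run a few tenths of a percentage point above the uniform
closed form (37.22% vs 36.60% at k = N = 100) precisely because distinct
people can share a Soundex form. Passing tests on the synthetic pool
therefore validate the machinery and the uniform-hash component of the
published figures, not the residual list-specific excess; reproducing
that excess requires the original list, which is not redistributed here.
Anonymity means per slot are unaffected (they are conservation laws,
`pool/N`), which is why those figures reproduce exactly.

## Numerical choices

- djb2 uses unsigned 32-bit wraparound; all digests lie in [0, 2³²).
- CRC-32 is `zlib.crc32`; an independent bit-at-a-time implementation
  serves as the oracle in tests.
- The combined "double hash" used only for benchmarking primitives takes
  djb2's low 16 bits as the upper half and CRC-32's low 16 bits as the
  lower half of a 32-bit digest.
- Slot search order is ascending from type 1; first free slot wins.
- Registries restore their previous state when an add fails.
- `build_registry` redraws samples (up to 100 attempts) until an encoding
  with zero failures is found, mirroring how one successful encoding per
  condition is selected for attack experiments.

## Limitations

Latin-script names only; no transliteration, nickname resolution or
fuzzy matching beyond Soundex. IDs are valid only within one study —
cross-study linkage is deliberately unsupported. Anonymity degrades with
small recruiting populations and with very large coding spaces (at
`N = 100,000` and a 103,472-name phonebook the mean is 1.03 hits per
slot: most participants are effectively identifiable). Biometric or
otherwise unstable representations cannot be coded, since two
measurements of the same person rarely agree byte-for-byte.
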