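# pseudoid

Short, unique, pseudonymous participant-linking IDs for multi-session
human-subjects studies — without a linking table.

## The problem

Longitudinal and multi-session studies must link each participant's data
across sessions. The usual device is a confidential linking table mapping
names to running numbers; if that table leaks, every participant is
de-anonymized, and merely storing it often triggers formal data-protection
approval procedures. `pseudoid` removes the table: a participant's ID is
recomputed from their name on demand, and the only persisted artifact — a
small JSON state file — contains no names.

## The scheme

A name is normalized (punctuation stripped, name parts sorted
alphabetically, each part replaced by its **full-length Soundex** code, so
"Rodman, David M", "david m rodman" and minor misspellings all coincide),
hashed with a 32-bit string hash, and **truncated** to the coding space
`{0, …, N−1}` by taking the digest mod `N`, with `N = c·L` for `L`
anticipated participants and coding factor `c` (default 10):

```
ID = Hash(Soundex(Sort(name))) mod N
```

The truncation is deliberately lossy: in a recruiting population of `P`
people, about `P/N` names share each ID (*k*-anonymity), so an adversary
holding the state file and a phonebook cannot tell which alias is the
participant. Inside the sample, however, IDs must be unique. Collisions
among participants are resolved with a family of 19 hash functions built
from djb2 and CRC-32 (reversed, rotated, and salted variants): the first
alternative hash type that yields a free slot is used, and the pair
`(hash type, validation code)` — the validation code being a second
truncated hash at `hash type + 10` — is attached to the colliding ID so a
later lookup can recognise the right alternative. Choosing `N ≈ 10·L`
keeps the chance of an unresolvable collision well below 1% while leaving
the IDs just 1 digit longer than the sample size requires.

## Worked example

```
$ pseudoid init study.json -L 20
initialized study: L=20, N=200 (3-digit IDs)
anonymity advisory: recruit from a population of at least 100 (k-anonymity 5 x L=20)

$ pseudoid add "Rodman, David M" --state study.json
warning: invalid characters removed from input: [',']
073

$ pseudoid add "Anne-Marie O'Neil" --state study.json
warning: invalid characters removed from input: ['-', "'"]
054

$ pseudoid lookup "david m rodman" --state study.json
073
```

The study holds at most `L = 20` participants coded into `N = 200` slots
(three-digit IDs). The advisory says that with the recommended
*k*-anonymity of 5 the participants should be recruited from a population
of at least `5 × 20 = 100` people, so that every ID has several plausible
owners. "Rodman, David M" receives ID `073`; the comma is stripped, the
name parts are sorted and phonetically coded, so the differently ordered,
differently cased `"david m rodman"` returns the same `073`. The state
file `study.json` records only the coding parameters and the ID list —
no names.

The same machinery is scriptable:

```python
from pseudoid import Study

study = Study.create(L=20)
study.add("Rodman, David M")   # -> 73
study.lookup("David M Rodman") # -> 73
study.save("study.json")
```

## Evaluation harness

`pseudoid.simulation` measures both sides of the integrity/anonymity
trade-off on a name pool (a loaded plain-text list, or a synthetic pool of
pairwise-phonetically-distinct person names with controllable duplicate
rates):

- `collision_rate` — raw birthday-problem collision probability of a
  single hash function at sample size `k` and space `N`;
- `encoding_success` — full add-sequence simulation: fraction of runs with
  no unresolvable collision, per-hash-type utilization, and the
  lookup-aliasing rate;
- `phonebook_attack` — attacks one encoding with a candidate list using
  the complete lookup semantics, reporting hits per slot, minimum /
  mean / maximum hits over assigned IDs (the minimum is the achieved
  *k*-anonymity), the fraction of candidates that are provably
  non-participants, and the unused-slot fraction;
- `sweep` — grids of `k × N` conditions written as tidy CSV, with
  optional plots.

All of these are exposed through the CLI (`simulate-collisions`,
`simulate-success`, `attack`, `gen-names`) and accept `--seed` for exact
reproducibility.

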