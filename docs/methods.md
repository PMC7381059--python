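# Methods

## Problem setting

One person accrues several electronic medical records (EMRs): across the
clinics and laboratories of a surveillance network, and within one site
when details change, aliases are used, or testing is anonymous. Pooled
analyses (testing frequency, proportion positive) are biased unless those
records are linked — but identifiers may not leave the sites. `privlink`
links records through irreversible hashed linkage keys computed at the
site, and quantifies how well that linkage works.

## Identifier canonicalization

Hashes admit only exact equality, so every tolerance is a
canonicalization applied before hashing:

* **Name cleaning.** Uppercase; within a whitespace token, non-alphabetic
  characters join name pieces (`O'Brien-Smith → OBRIENSMITH`); stop words
  (titles: DR, MR, MRS, … — an editable 16-entry list) are dropped; the
  longest remaining token is kept (ties: first). Keeping the longest token
  is a deterministic rule that is robust to recorded middle names;
  it is configurable data, not code.
* **Nickname resolution.** A bundled ~150-pair nickname→canonical table
  (editable CSV) maps BILL→WILLIAM etc.; canonical forms and unknown
  tokens pass through, so resolution is idempotent. Resolution applies to
  both name fields symmetrically — necessary for the swapped-name
  invariance of keys 3 and 4. A side effect is that a surname that
  collides with a nickname (e.g. KIM) is also resolved; this is
  deterministic and identical for all records, so it cannot break
  linkage, it only relabels the canonical form.
* **Phonetic coding.** The primary double-metaphone code (4 characters),
  implemented in `privlink.phonetics` from the published rule set and
  validated against hand-traced vectors. Only the primary code is used:
  one key per type per record; using the alternate code as a second
  variant key would double key volume for marginal recall on names with
  genuinely ambiguous pronunciation.
* **Date of birth.** Calendar-validated; an impossible combination
  (31 February) makes the *day* missing and is reported in the validation
  log. For the name-based key a transposition-canonical form is used:
  when day and month are both ≤ 12 and differ, the smaller value is
  placed in the day slot, so 03/05 and 05/03 coincide; the
  canonicalization is a normal form (re-applying it changes nothing).
* **Sex** maps to M / F / X (any other non-empty value); **Medicare
  numbers** must contain 10 digits after stripping separators, and the
  first five digits of the card number are used (the exact five are not
  externally specified; the first five are deterministic, and the offset
  is configurable — colliding family cards are disambiguated by the other
  key components).

Missingness is always `None`/empty-field, never a sentinel value.

## Key hashing

Keys are HMAC-SHA256 digests of the ordered canonical components, joined
by a unit-separator byte that cannot occur in any component (preventing
concatenation ambiguity), under a non-empty secret seed supplied as a
byte string and never emitted anywhere. Digests are 64 lowercase hex
characters (truncation configurable). Each key type is salted with a type
tag, so equal component lists of different key types can never collide. A
key is generated only when every component is present; partial input is
never hashed. Two sites link only if they share the seed; without it the
keys are irreversible, and the deidentified output retains nothing beyond
record/site IDs, normalized sex and birth year.

## Linkage

1. **Candidate pairs** — exact-equality inverted index per key type;
   output provably equal to brute-force all-pairs comparison (tested on
   random instances). Missing keys never match.
2. **Acceptance** — six approaches: accept all; matching year of birth;
   matching sex; both; ≥ 2 matching key types; key 3 plus matching sex.
   A pair with missing sex/birth year **fails** a demographic filter by
   default (strictness favours specificity; a lenient flag inverts this).
3. **Link IDs** — connected components of the accepted-pair graph
   (networkx), computed *after* filtering, so a rejected pair never
   merges clusters through a shared neighbour. The link ID is the
   smallest record ID in the component: labels are deterministic and
   independent of input order. No one-to-one constraint is imposed — one
   record may genuinely match many.

## Evaluation

Scoring is per record against a gold-standard clustering. A truly-linked
record is *correctly linked* if the tool places it with ≥ 1 true
co-member (an all-co-members variant is available; the at-least-one
definition is what record-level counting implies — a single missed pair
costs exactly its two records). A truly-single record is *correctly
unlinked* if the tool links it to nothing. Sensitivity and specificity
condition on the truth; PPV and NPV condition on the tool's output.
Percentages are half-up rounded to 2 decimals; empty denominators are
reported as not estimable, never as 0 or 100.

Gold standards:

* **registry** — records sharing an auxiliary person ID (study enrolment
  registry) form one cluster; everything else is a singleton; a record
  under two person IDs is an error.
* **specimen** — a clinic and a laboratory record match iff they share
  the laboratory specimen ID and year of birth and their test dates
  differ by ≤ 7 days (inclusive; recorded dates for one specimen commonly
  differ between systems). Matches merge transitively; unmatched records
  are excluded because their true status cannot be verified — hence
  specificity is not directly measurable from this design.

## Discordant-serology audit

After infection, an HIV or hepatitis C antibody test never reverts to
negative; assay error is assumed negligible. The audit exploits this:

1. records whose own history is already discordant (negative antibody
   ≥ `window_days` after a positive within the record, default 7) are
   excluded — their discordance predates linkage;
2. only linked clusters containing an antibody result dated after an
   initial positive are retained (HIV: the first positive western blot;
   HCV: the first positive antibody) — discordance is observable only
   after a positive;
3. a retained cluster is discordant if any negative antibody occurs
   ≥ `window_days` after any positive (the window applies at
   classification, not at retention);
4. the records carrying the offending negatives are counted incorrectly
   matched — unless a strict majority (> 50%) of the post-initial-positive
   antibody results are negative, in which case the positive-result
   records are the intruders; a tie leaves the cluster discordant with
   the default attribution.

PPV = concordant retained records / retained records. Specificity then
follows from the Bayes identity `Sp = 1 − Se·π·(1−PPV)/(PPV·(1−π))`,
clamped to [0, 1], with the prevalence π of truly-linked records supplied
explicitly (from synthetic truth, or externally); the identity is exact
at the level of record counts within the population the PPV refers to.

**Identifiability.** The audit sees only serology-bearing records, counts
one intruder per detected false link, and detects a false link only when
the negative falls ≥ 7 days after a positive in the merged history. The
estimator-recovery experiment therefore validates the chain under the
conditions where it is unbiased: scoring restricted to the
serology-bearing subpopulation, false links attaching a seronegative
singleton to an auditable seropositive cluster, detectability and
majority-attribution guaranteed by construction. Under those conditions
the audit PPV equals the measured PPV and the inverted specificity equals
the measured specificity (up to Monte-Carlo noise); outside them — false
links among seronegatives, concordance by timing, clusters without
auditable histories — the audit PPV is an approximation, which is why the
validation bands are stated as ±2 standard errors.

## Synthetic cohorts

The generator emulates, per seeded configuration: person identities drawn
from bundled pools (~260 given names, ~310 surnames — pool size affects
only name diversity, not behaviour); clinic attendance by per-site visit
probability (every person attends ≥ 1 clinic); within-site duplicate EMRs
(default rate 0.02 — an order-of-magnitude guess, as real rates are
unpublished); per-site corruption drawn independently per record:
Medicare blanking, nickname substitution, single-character typos split
between phonetic-preserving and phonetic-breaking edits (default 50/50 —
the two regimes separate key-3-survivable from key-3-breaking errors),
day/month transposition (only when it yields a valid date), year-only
dates; clinic→laboratory specimen flows (each clinic test mirrored to one
laboratory record sharing the specimen ID, with 0–7 days of date jitter,
default 2); and serology histories strictly consistent with each person's
status — seronegative before infection, an initial positive western blot
(HIV) or antibody (HCV) at diagnosis, positive antibody thereafter, no
assay error. Distinct persons are guaranteed distinguishable: Medicare
prefixes are assigned without repetition and identities whose
phonetic-name + canonical-date signature collides with an earlier person
are resampled — chance doppelgängers would silently corrupt the ground
truth against which linkage is scored (real twins/shared identifiers are
a documented limitation, not a generator feature).

The default site mix is 7 general clinics with near-complete Medicare
recording, one sexual-health clinic at ~46% completeness, and 4
laboratories spanning ~3%–96% completeness — qualitatively the spread a
mixed clinic/laboratory network exhibits.

What the generator does **not** model: demographically realistic
populations, assay sensitivity/specificity, correlated corruption between
a person's records, shared identifiers between persons (twins, family
Medicare cards), or within-person identifier drift over time. Passing
tests therefore demonstrate the pipeline's correctness and its response
to identifier quality, not performance guarantees on any real network.

## Validation problem sizes and numerical choices

The validation suite uses: a 3700-record registry worked example; a
1000-person clean-limit cohort (clinic-only, so single-clinic patients
remain truly single); a 2000-person cohort with one laboratory blanking
Medicare at 97% (key-3-only fraction checked within ±2 binomial SE);
100 random ≤ 200-record instances against brute-force pair and scoring
oracles; a ~6000-person (~10,000 serology-bearing records) estimator
recovery with 60 injected false links; and 1000 random identities for the
key-3 invariance sweep. A 10⁵-identity sweep checks for full-keyset
collisions (none expected or observed). All experiments derive their
randomness from a single seed argument.

Numerical conventions: half-up rounding to 2 decimals for reported
percentages; date-window comparisons inclusive (≥ 7 days discordant,
≤ 7 days specimen match); the specificity inversion validated to 1e−10
against the forward identity on a (Se, Sp, π) grid and clamped to [0, 1];
record IDs ordered lexicographically wherever a deterministic tie-break
is needed.

## Known limitations

* The audit PPV refers to the serology-bearing subpopulation; applying
  the inversion with a whole-population prevalence mixes populations and
  the result is approximate to the extent false links correlate with
  serostatus.
* Records with only one linkage key (no Medicare number) are invisible to
  the two-or-more-keys approach by construction.
* The phonetic encoder follows the published double-metaphone rules and
  agrees with hand-traced vectors; exotic names may diverge from other
  implementations, but both sides of a key comparison use the same
  encoder, so linkage behaviour is internally consistent.
* The secret seed is a shared symmetric secret; key management, transport
  security and governance are out of scope.
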