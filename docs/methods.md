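# Methods

## The classification scheme

A topology scheme reduces a protein to its length plus a list of
annotated intervals and sites, split into three categories:

* **Regions**: long structural/functional intervals (domains, repeats).
* **Motifs**: short linear intervals — signal peptides, transmembrane
  segments, coiled coils, low-complexity and compositionally biased
  stretches, intrinsically disordered segments and disordered binding
  segments, SLiM-class motifs (cleavage, degradation, targeting,
  nuclear-traffic, docking/ligand/binding, activity-related), with
  `other_motif` as the 17th, catch-all type.
* **Markups**: single-residue annotations — the glycosylation family
  (N-, O-, GAG, C-mannosylation, O-fucosylation, unspecified), other PTMs
  (hydroxylation, prenylation, acylation, GPI, lipidation, acetylation,
  methylation, amidation, pyroglutamate, sulfation, D-isomerization),
  bonds and conjugations (disulfide, cross-link, SUMO, ubiquitin),
  processing/trafficking sites, binding/ligand/docking/interaction
  sites, catalytic annotations, the three specific phospho-residues plus
  unspecified phosphorylation, and a catch-all `other` — 47 types total.

The controlled vocabulary ships as two TSV files (`vocabulary.tsv`:
pattern → category + canonical type; `glyphs.tsv`: canonical type →
glyph id, colour, head style) and is user-extensible by constructing a
`Vocabulary` from custom tables.

### Matching rules and their edge cases

Keywords are matched case-insensitively as substrings; the longest
matching pattern wins, ties break alphabetically, and when the same
pattern exists in two categories a single-site feature prefers the
markup reading. Interval features never match markup patterns (a markup
is by definition one residue). These rules make `phospho-serine` beat
the generic `phospho`, and required one deliberate asymmetry in the
pattern table: generic family patterns are kept *shorter* than their
specific siblings (`glycos` vs `n-linked`) so specificity wins under
longest-match. Unmatched keywords fall back to `other_motif` (intervals)
or `other` (sites) with a logged warning — classification never hard
fails on free text; only an explicitly declared, invalid canonical type
in a curated table does.

Bond-type database annotations (disulfide bridges, isopeptide
cross-links) span their two partner cysteines/lysines in UniProt and
GenPept feature tables; they are expanded into two single-residue
markups, one per partner, because a lollipop per bonded residue is what
a linear diagram can show. Whole-protein bookkeeping entries (`Chain`,
variants, mutagenesis, conflicts) are skipped at ingestion.

### Shape and colour rules

Region boxes encode length: repeats are jagged; otherwise > 200 aa is
pointed, 35–200 aa (boundaries inclusive) curved, < 35 aa straight. The
three ranges tile the positive integers exactly, which fixes the
boundary reading. Region colours are assigned per protein: the *n*
unique labels, in first occurrence order, get hues *i/n* around the HSV
colour wheel (S = 0.6, V = 0.9), so identically named regions share a
colour within a protein but not across proteins. Motif and markup
colours are fixed per canonical type in `glyphs.tsv` (evenly spaced
hues), with markup head styles cycling through circle, square, diamond,
arrow, pentagon and line.

## Ingestion

**Database records.** UniProt is parsed from the REST JSON form, with a
small line reader for the flat-text form as fallback; GenPept flat files
are parsed with Biopython's GenBank reader (coordinates converted from
its 0-based half-open form to the 1-based inclusive convention used
throughout). Live fetching (UniProt REST / NCBI efetch) is optional and
cached; every code path works offline from fixture files.

**Prediction servers.** Server output formats drift across versions, so
each of the seven dialects is pinned: the accepted format is the one
documented in `docs/formats.md` (dialect version 1) and exemplified by
the fixture generator. Score handling per resource: the site predictors
(NetNGlyc, NetOGlyc, NetPhos) and the disorder predictors (IUPred,
ANCHOR) report [0, 1] propensities with 0.5 as the conventional decision
boundary — that is the default cutoff; SMART rows are filtered by
e-value only when a ceiling is supplied; ELM has no default cutoff;
ScanSite results are passed through (stringency is chosen server-side).
IUPred/ANCHOR per-residue scores are segmented into maximal runs of
consecutive residues at-or-above the cutoff; each run becomes one
disorder (or disordered-binding) interval carrying the run's mean score.
Note that the *number* of such intervals is not monotone in the cutoff —
raising it can split a run in two — while the number of covered residues
is; tests assert the latter.

**Curated tables.** Required columns `name, type, start, end`; optional
`category, colour, source, score, is_repeat`. A row with an explicit
category bypasses classification (its `type` must then be a canonical
type key — this is the one hard-failing path); other rows have their
`type` keyword classified. csv/tsv files may carry `# key: value`
metadata header lines (`protein`, `length`, `accession`).

## Scheme JSON and determinism

The emitted document follows the Pfam domain-graphics layout (`length`,
`regions[]` with `start/end/text/colour/startStyle/endStyle`, `motifs[]`
with colour and opacity, `markups[]` with `headStyle` and colours). Each
entry carries a `metadata` sub-object (label, canonical type, source,
score) — an extension chosen so that decoding is exact rather than
lossy; `decode(encode(x))` reproduces the feature table field-for-field,
and shapes are re-derived from lengths on re-encoding. Serialization is
canonical (sorted keys, fixed indentation, integer coordinates, #RRGGBB
colours), so identical schemes produce byte-identical JSON. xlsx output
is made byte-deterministic by pinning workbook timestamps and repacking
the archive with constant entry metadata.

## Rendering

SVG 1.1, generated with the standard library XML tree (well-formed by
construction). Horizontal geometry is strictly linear: residue *p*
occupies `[(p-1)·px, p·px]` with `px = px_per_aa × rescale`, so changing
the amino-acid pixel size stretches (zooms) the scheme and `rescale`
scales the whole drawing; figure padding lives only in the viewBox so
element coordinates stay exactly proportional. Visual constants
(backbone 14 units, region boxes 18, markup stems 18, two stagger tiers
10 units apart, 10 pt sans-serif) sit in one `GEOMETRY` block; they are
this renderer's declared defaults, not inferred from any other tool.
Lollipop heads that would collide are staggered to a second tier in
discovery order; further collisions drop the stem and draw the head
against the backbone, so dense PTM clusters stay readable. The legend
has one row per distinct type (regions keyed by label), with the
category in brackets.

## Synthetic fixtures: what they do and do not show

`fixtures.generate_fixtures(seed, out_dir)` emulates every input dialect
for one synthetic protein (length drawn in 400–800 aa: a typical
single-pass receptor scale): database records with a signal peptide, two
domains, a transmembrane segment and glycosylation/phosphorylation
sites; predictor outputs whose scores deliberately straddle the 0.5
default cutoffs; disorder score vectors with planted above-cutoff runs;
and a curated table mixing explicit-category and keyword rows. A
manifest records expected parse counts and planted runs, so parser tests
check against the generator's own bookkeeping rather than hand-counted
constants. What the fixtures do *not* emulate: real servers' header
noise and version banners (the dialects are pinned to the documented
core tabular form), real sequence content (only lengths and coordinates
matter to a topology scheme), and genuinely contending annotations
beyond exact duplicates. Passing tests therefore demonstrate correct
parsing, classification, codec and rendering behaviour on the pinned
dialects — not robustness to arbitrary third-party format drift.

The packaged CD45 records are synthetic stand-ins (marked `synthetic` in
the filename and record) carrying the true 1306-aa length and a
representative subset of the real annotations; the GenPept stand-in's
sequence is random because only its length is consumed.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere; conversions are confined
  to the GenPept reader and the SVG x-axis.
* Duplicate collapse keys on (category, type, start, end); the survivor
  is chosen by source precedence UniProt > GenPept > predictors > custom,
  ties by input order. Overlapping-but-not-identical intervals are all
  kept — reconciling near-duplicates is a curation decision, not one the
  tool should make silently.
* Feature sort is the stable (start, end, category) order with regions
  before motifs before markups at equal coordinates — bottom-to-top
  drawing order; the ordering of overlapping regions is otherwise a free
  choice.
* Default motif opacity 0.8: translucent enough to show a region
  underneath, opaque enough to read the motif colour.
* Problem sizes in the test-suite and acceptance run (200 round-trip
  schemes, 50-point cutoff sweeps, 25 rendered schemes) were chosen as
  the smallest sizes that still exercise every glyph type and collision
  path; all checks complete in seconds.

## Known limitations

* The keyword vocabulary is a reconstruction from the published category
  enumerations plus canonical UniProt feature keys; it is deliberately
  user-extensible because no published exhaustive keyword list exists.
* Only the pinned dialect of each prediction server is accepted; saved
  outputs from other server versions may need light reformatting.
* Third-party Pfam-graphics documents without the `metadata` extension
  decode with generic canonical types (`region`/`other_motif`/`other`).
* No cross-protein colour persistence, by design.
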