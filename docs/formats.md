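# Input format reference (dialect version 1)

All parsers accept UTF-8 plain text. Lines that are empty or start with
`#` are ignored except where noted. Positions are 1-based inclusive.
These dialects are pinned: the fixture generator
(`protoscheme.fixtures`) emits exactly these forms, and the parsers are
contracted to them.

## Database records

**UniProt** — preferred form is the REST JSON record; the consumed keys
are `primaryAccession`,
`proteinDescription.recommendedName.fullName.value`, `sequence.length`
and `features[]` (`type`, `description`,
`location.start.value`/`end.value`). The flat-text form is accepted as a
fallback; consumed lines are `ID` (length), `DE   RecName: Full=` and
the `FT` table (key, `start[..end]`, following `/note="..."`).

**GenPept** — a GenBank-dialect flat file with `LOCUS`, `FEATURES` and
an `ORIGIN` sequence block (required by the parser). Consumed feature
keys: everything except `source`; the keyword is built from the feature
type plus `region_name`, `site_type` and `note` qualifiers.

In both databases, `Chain`, variant/mutagenesis/conflict entries are
skipped, and bond-type features (disulfide, cross-link) spanning two
residues are split into one site per partner.

## Prediction servers

One record per line; columns split on tabs when present, otherwise on
whitespace.

| Resource | Columns | Emitted feature | Cutoff semantics |
|---|---|---|---|
| SMART | `name=N start=S end=E evalue=V type=T` tokens | domain interval `"{name} domain"` | e-value ceiling; off by default |
| ELM | `elm_identifier  start  stop  score` (header line allowed) | motif interval keyed by ELM class id (`LIG_…`, `DEG_…`, …) | score floor; off by default |
| NetNGlyc | `name  pos  sequon  potential  jury  answer` | N-glycosylation site | potential ≥ 0.5 |
| NetOGlyc | GFF-like: `name  method  CARBOHYD  start  end  score  .  .  comment` | O-glycosylation site | score ≥ 0.5 |
| NetPhos | `name  pos  residue(S/T/Y)  context  score  kinase` | phospho-Ser/Thr/Tyr site | score ≥ 0.5 |
| ScanSite | `group  motif_name  site(e.g. Y1216)  score [percentile]` | phospho site or motif-named site | none (passed through) |
| IUPred/ANCHOR | `pos  residue  iupred [anchor]` per residue | maximal runs of residues ≥ cutoff: disorder (column 3) and disordered-binding (column 4) intervals, scored by the run mean | both ≥ 0.5 |

Rows with positions beyond the declared protein length raise a
coordinate error naming the row.

## Curated feature tables (csv / tsv / xlsx)

Header row required. Columns:

* required — `name` (display label), `type` (keyword or canonical type
  key), `start`, `end`;
* optional — `category` (one of `region|motif|markup`; when present,
  `type` must be a canonical type key and is not re-classified),
  `colour` (`#RRGGBB` override, collected into metadata), `source`,
  `score`, `is_repeat` (`true/false/1/0/yes/no`).

csv/tsv files may begin with metadata comment lines:

```
# protein: Receptor-type tyrosine-protein phosphatase C
# length: 1306
# accession: P08575
```

`export_table` writes this same schema, so exported tables re-import
losslessly.

## Scheme JSON

See `src/protoscheme/data/schema.json` for the normative structural
description and `protoscheme.codec.validate_document` for the
executable check.
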