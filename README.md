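# protoscheme

Generate publication-ready **protein topology schemes** — linear diagrams
of a protein with its domains, motifs and single-residue sites drawn along
the sequence axis — from three kinds of evidence:

1. **Database records**: UniProt entries (JSON or flat text) and NCBI
   GenPept flat files, by accession;
2. **Raw prediction results**: saved text output of SMART (domains), ELM
   (short linear motifs), NetNGlyc / NetOGlyc / NetPhos / ScanSite
   (single-site PTM predictions) and IUPred/ANCHOR (per-residue disorder
   scores), each with its own score cutoff;
3. **Curated feature tables** in xlsx, csv or tsv.

The target users are protein scientists who need to combine annotations
from several — sometimes contending — resources into one concise figure,
and do it for many proteins at once.

## The model

Every feature is classified by a **controlled keyword vocabulary** into
one of three categories:

* **Regions** — domains, repeats and other long functional intervals,
  drawn as shaped boxes on the protein backbone. The box shape encodes
  the length: *pointed* ends for long regions (> 200 aa), *curved* for
  medium regions (35–200 aa), *straight* for short ones (< 35 aa), and
  *jagged* for repeats. Region colours are a rainbow gradient assigned
  anew per protein, with same-named regions sharing a colour.
* **Motifs** (17 canonical types) — short linear intervals: signal
  peptide, coiled coil, low complexity, intrinsic disorder, disordered
  binding, transmembrane part, and so on; drawn as translucent bars.
* **Markups** (47 canonical types) — single-residue annotations:
  N-/O-glycosylation, phospho-serine/-threonine/-tyrosine, disulfide
  bond, active site, and many more; drawn as lollipops with a per-type
  head glyph and colour.

Classification is case-insensitive substring matching of the source
keyword against the vocabulary patterns, longest pattern winning, with a
warning-level fallback (`other_motif` / `other`) for unmatched keywords.
The classified scheme is serialized as a Pfam-domain-graphics-style JSON
document (`length` + `regions[]` + `motifs[]` + `markups[]`; normative
schema in `src/protoscheme/data/schema.json`), which decodes losslessly
back to the feature table and renders to SVG with tunable amino-acid
pixel size, proportional rescaling and motif opacity.

## Worked example

The packaged stand-in record for human CD45 (receptor-type
tyrosine-protein phosphatase C, UniProt P08575; a synthetic copy carrying
the true length and representative features):

```python
from importlib import resources
from pathlib import Path
from protoscheme import scheme_from_record, encode_scheme
from protoscheme.render import render_svg

data = Path(str(resources.files("protoscheme.data")))
scheme = scheme_from_record("P08575", "uniprot", offline_fixture=data)
print(f"{scheme.name} ({scheme.accession}), {scheme.length} aa, "
      f"{len(scheme.features)} features")
for f in scheme.features[:6]:
    print(f"  {f.category.value:<7}{f.type_key:<17}{f.start}..{f.end}  {f.label}")
doc = encode_scheme(scheme)
print("regions:", len(doc["regions"]), "motifs:", len(doc["motifs"]),
      "markups:", len(doc["markups"]))
svg = render_svg(doc, include_legend=True)
```

prints

```
Receptor-type tyrosine-protein phosphatase C (P08575), 1306 aa, 27 features
  motif  signal_peptide   1..23  Signal
  region domain           24..577  Topological domain: Extracellular
  markup o_glycosylation  47..47  Glycosylation: O-linked (GalNAc...) threonine
  markup n_glycosylation  59..59  Glycosylation: N-linked (GlcNAc...) asparagine
  markup o_glycosylation  92..92  Glycosylation: O-linked (GalNAc...) threonine
  markup n_glycosylation  111..111  Glycosylation: N-linked (GlcNAc...) asparagine
regions: 6 motifs: 2 markups: 19
```

i.e. the 1306-aa receptor with its cleavable signal peptide classified
as a motif, the extracellular part and the intracellular phosphatase
domains as regions, and the glycosylation/phosphorylation sites as
markups. The same pipeline is available from the shell:

```sh
protoscheme --accession P08575 --offline src/protoscheme/data --out-dir out/
protoscheme --table my_features.csv --out-dir out/
protoscheme --input netphos=raw/netphos.txt --cutoff netphos=0.7 \
            --length 1306 --name CD45 --out-dir out/
```

Each invocation writes the scheme JSON, the feature table (csv) and the
rendered SVG. `python -m protoscheme.fixtures OUT --seed 7` generates a
full synthetic fixture tree (mock records, all seven predictor outputs,
curated tables and a manifest of expected parse counts).

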