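"""Deterministic synthetic fixtures for offline testing.

:func:`generate_fixtures` writes, for one seeded synthetic protein, every
input dialect the package accepts: a mock UniProt JSON record, a mock
GenPept flat file, raw outputs for all seven prediction servers (with
scores deliberately straddling the default cutoffs), and a curated
feature table in csv/tsv/xlsx. A ``manifest.json`` records the expected
parse counts and the planted disorder runs, so tests can check every
parser against the generator's own bookkeeping. The same seed always
yields a byte-identical fixture tree.

:func:`random_scheme` builds random but valid protein schemes for
round-trip property tests.
"""

from __future__ import annotations

import json
import random
from pathlib import Path
from .classify import default_vocabulary
from .feature_model import Category, FeatureRecord, ProteinScheme, Source

__all__ = ["generate_fixtures", "random_scheme"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_KINASES = ["PKC", "PKA", "CKII", "CDK5", "SRC", "EGFR"]
_ELM_CLASSES = [
    "LIG_SH2_STAT5", "LIG_SH3_3", "MOD_GSK3_1", "TRG_ER_KDEL_1",
    "DEG_APCC_DBOX_1", "CLV_PCSK_FUR_1", "DOC_MAPK_gen_1",
]
_SMART_DOMAINS = ["PTPc", "FN3", "IG_like", "SH2", "KRINGLE"]
_REGION_LABELS = ["Kinase domain", "FN3", "Ig-like", "PDZ", "SH3", "WD40"]


def _rng_scores(rng: random.Random, n: int, lo=0.05, hi=0.95) -> list[float]:
    return [round(rng.uniform(lo, hi), 3) for _ in range(n)]


def _distinct_positions(rng: random.Random, n: int, length: int) -> list[int]:
    return sorted(rng.sample(range(5, length - 4), n))


def _write(path: Path, text: str) -> None:
    path.write_text(text, encoding="utf-8")


def _uniprot_json(name: str, accession: str, length: int, features) -> str:
    doc = {
        "primaryAccession": accession,
        "proteinDescription": {
            "recommendedName": {"fullName": {"value": name}}
        },
        "sequence": {"length": length},
        "features": [
            {
                "type": ftype,
                "description": desc,
                "location": {"start": {"value": s}, "end": {"value": e}},
            }
            for ftype, desc, s, e in features
        ],
    }
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def _genpept_flat(name: str, accession: str, length: int, seq: str, features) -> str:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from io import StringIO

    record = SeqRecord(
        Seq(seq),
        id=accession,
        name=accession.split(".")[0].replace("_", "")[:16],
        description=name,
        annotations={
            "molecule_type": "protein",
            "date": "01-JAN-2000",
            "accessions": [accession.split(".")[0]],
        },
    )
    for ftype, quals, s, e in features:
        record.features.append(
            SeqFeature(SimpleLocation(s - 1, e), type=ftype, qualifiers=quals)
        )
    out = StringIO()
    SeqIO.write(record, out, "genbank")
    return out.getvalue()


def _plant_runs(
    rng: random.Random, length: int, n_runs: int, forbidden: set[int]
) -> list[tuple[int, int]]:
    """Disjoint intervals separated by >= 2 residues, avoiding `forbidden`."""
    runs: list[tuple[int, int]] = []
    attempts = 0
    while len(runs) < n_runs and attempts < 200:
        attempts += 1
        width = rng.randint(4, 25)
        start = rng.randint(1, max(1, length - width))
        end = start + width - 1
        span = set(range(start - 2, end + 3))
        if span & forbidden:
            continue
        forbidden |= span
        runs.append((start, end))
    return sorted(runs)


def generate_fixtures(seed: int, out_dir) -> dict:
    """Write the full fixture tree for one synthetic protein; returns the
    manifest (also saved as ``manifest.json``)."""
    rng = random.Random(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    length = rng.randint(400, 800)
    name = "Synthetic receptor-like protein 1"
    up_acc, gp_acc = "P99999", "NP_999999.1"
    seq = "M" + "".join(rng.choice(_AA) for _ in range(length - 1))

    # --- database records -------------------------------------------------
    tm_start = rng.randint(length // 2, length // 2 + 60)
    dom1 = (30, 30 + rng.randint(180, 220))
    dom2 = (dom1[1] + 20, dom1[1] + 20 + rng.randint(60, 120))
    glyc_sites = _distinct_positions(rng, 6, length // 2)
    phos_site = rng.randint(tm_start + 40, length - 10)
    up_features = [
        ("Signal", "", 1, 22),
        ("Domain", f"{rng.choice(_REGION_LABELS)} 1", *dom1),
        ("Domain", f"{rng.choice(_REGION_LABELS)} 2", *dom2),
        ("Transmembrane", "Helical", tm_start, tm_start + 21),
        ("Modified residue", "Phosphoserine; by PKC", phos_site, phos_site),
    ] + [
        ("Glycosylation", "N-linked (GlcNAc...) asparagine", p, p)
        for p in glyc_sites
    ]
    _write(out / f"{up_acc}.json", _uniprot_json(name, up_acc, length, up_features))

    gp_features = [
        ("source", {"organism": ["synthetic construct"]}, 1, length),
        ("sig_peptide", {}, 1, 22),
        ("Region", {"region_name": ["Kinase domain 1"]}, dom1[0], dom1[1]),
        ("Region", {"region_name": ["Transmembrane region"]}, tm_start, tm_start + 21),
        ("Site", {"site_type": ["phosphorylation"]}, phos_site, phos_site),
        ("Site", {"site_type": ["glycosylation"]}, glyc_sites[0], glyc_sites[0]),
    ]
    _write(out / f"{gp_acc}.gp", _genpept_flat(name, gp_acc, length, seq, gp_features))

    files: dict[str, dict] = {}

    # --- SMART: domain intervals, e-value filter off by default ----------
    n_smart = rng.randint(2, 4)
    smart_lines = ["# SMART result, dialect v1"]
    pos = 25
    for i in range(n_smart):
        width = rng.randint(60, 120)
        start = pos + rng.randint(0, 30)
        end = min(start + width, length - 5)
        pos = end + 5
        ev = f"{rng.uniform(1e-40, 1e-5):.2e}"
        smart_lines.append(
            f"name={rng.choice(_SMART_DOMAINS)} start={start} end={end} "
            f"evalue={ev} type=SMART"
        )
    _write(out / "smart.txt", "\n".join(smart_lines) + "\n")
    files["smart.txt"] = {"source": "smart", "rows": n_smart,
                          "expected_at_default": n_smart}

    # --- ELM: motif intervals, no default cutoff --------------------------
    n_elm = rng.randint(3, 6)
    elm_lines = ["elm_identifier\tstart\tstop\tscore"]
    for _ in range(n_elm):
        start = rng.randint(1, length - 12)
        stop = start + rng.randint(3, 11)
        elm_lines.append(
            f"{rng.choice(_ELM_CLASSES)}\t{start}\t{stop}\t"
            f"{round(rng.uniform(0.1, 0.99), 3)}"
        )
    _write(out / "elm.tsv", "\n".join(elm_lines) + "\n")
    files["elm.tsv"] = {"source": "elm", "rows": n_elm,
                        "expected_at_default": n_elm}

    # --- NetNGlyc / NetOGlyc / NetPhos: sites straddling the 0.5 cutoff ---
    n_ngl = rng.randint(4, 8)
    scores = _rng_scores(rng, n_ngl)
    positions = _distinct_positions(rng, n_ngl, length)
    lines = ["# NetNGlyc output, dialect v1"]
    for p, s in zip(positions, scores):
        sequon = "N" + rng.choice("AGV") + rng.choice("ST")
        lines.append(f"{up_acc} {p} {sequon} {s:.3f} (9/9) {'+' if s >= 0.5 else '-'}")
    _write(out / "netnglyc.txt", "\n".join(lines) + "\n")
    files["netnglyc.txt"] = {
        "source": "netnglyc", "rows": n_ngl,
        "expected_at_default": sum(1 for s in scores if s >= 0.5),
    }

    n_ogl = rng.randint(4, 8)
    scores = _rng_scores(rng, n_ogl)
    positions = _distinct_positions(rng, n_ogl, length)
    lines = []
    for p, s in zip(positions, scores):
        lines.append(
            f"{up_acc}\tnetOGlyc\tCARBOHYD\t{p}\t{p}\t{s:.3f}\t.\t.\t"
            + ("#POSITIVE" if s >= 0.5 else ".")
        )
    _write(out / "netoglyc.tsv", "\n".join(lines) + "\n")
    files["netoglyc.tsv"] = {
        "source": "netoglyc", "rows": n_ogl,
        "expected_at_default": sum(1 for s in scores if s >= 0.5),
    }

    n_phos = rng.randint(5, 10)
    scores = _rng_scores(rng, n_phos)
    positions = _distinct_positions(rng, n_phos, length)
    lines = ["# NetPhos output, dialect v1"]
    for p, s in zip(positions, scores):
        res = rng.choice("STY")
        ctx = "".join(rng.choice(_AA) for _ in range(5))
        lines.append(
            f"{up_acc} {p} {res} {ctx} {s:.3f} {rng.choice(_KINASES)}"
        )
    _write(out / "netphos.txt", "\n".join(lines) + "\n")
    files["netphos.txt"] = {
        "source": "netphos", "rows": n_phos,
        "expected_at_default": sum(1 for s in scores if s >= 0.5),
    }

    # --- ScanSite: passed through unfiltered ------------------------------
    n_scan = rng.randint(3, 6)
    positions = _distinct_positions(rng, n_scan, length)
    lines = ["# ScanSite output, dialect v1"]
    for p in positions:
        res = rng.choice("STY")
        motif = rng.choice(["Baso_ST_kin", "Y_kin_general", "SH2_binding"])
        lines.append(f"Kinase\t{motif}\t{res}{p}\t{round(rng.uniform(0.2, 0.8), 4)}")
    _write(out / "scansite.tsv", "\n".join(lines) + "\n")
    files["scansite.tsv"] = {"source": "scansite", "rows": n_scan,
                             "expected_at_default": n_scan}

    # --- IUPred/ANCHOR: per-residue scores with planted runs --------------
    forbidden: set[int] = set()
    iupred_runs = _plant_runs(rng, length, rng.randint(2, 3), forbidden)
    anchor_runs = _plant_runs(rng, length, rng.randint(1, 2), forbidden)
    iup = [round(rng.uniform(0.02, 0.45), 3) for _ in range(length)]
    anc = [round(rng.uniform(0.02, 0.45), 3) for _ in range(length)]
    for s, e in iupred_runs:
        for i in range(s - 1, e):
            iup[i] = round(rng.uniform(0.5, 0.98), 3)
    for s, e in anchor_runs:
        for i in range(s - 1, e):
            anc[i] = round(rng.uniform(0.5, 0.98), 3)
    lines = ["# POS\tRES\tIUPRED2\tANCHOR2"]
    for i in range(length):
        lines.append(f"{i + 1}\t{seq[i]}\t{iup[i]:.3f}\t{anc[i]:.3f}")
    _write(out / "iupred_anchor.txt", "\n".join(lines) + "\n")
    files["iupred_anchor.txt"] = {
        "source": "iupred_anchor", "rows": length,
        "expected_at_default": len(iupred_runs) + len(anchor_runs),
    }

    # --- curated tables (identical content in three formats) --------------
    header = ["name", "type", "start", "end", "category", "source", "score"]
    rows = [
        ["Kinase domain", "domain", dom1[0], dom1[1], "region", "custom", ""],
        ["Signal peptide", "Signal peptide", 1, 22, "", "custom", ""],
        ["TM helix", "Transmembrane", tm_start, tm_start + 21, "", "custom", ""],
        ["P-site", "phospho_serine", phos_site, phos_site, "markup", "custom", 0.9],
        ["N-glyc", "N-linked (GlcNAc...)", glyc_sites[0], glyc_sites[0], "", "custom", 0.8],
    ]
    meta_lines = [f"# protein: {name}", f"# length: {length}"]

    def cell(v):
        return "" if v == "" else str(v)

    for fmt, sep in (("csv", ","), ("tsv", "\t")):
        body = [sep.join(header)] + [sep.join(cell(v) for v in r) for r in rows]
        _write(out / f"features.{fmt}", "\n".join(meta_lines + body) + "\n")
    from ._xlsx import write_rows

    write_rows([header] + [[None if v == "" else v for v in r] for r in rows],
               out / "features.xlsx")
    files["features.csv"] = {"source": "table", "rows": len(rows),
                             "expected_at_default": len(rows)}

    manifest = {
        "seed": seed,
        "protein": {
            "name": name,
            "length": length,
            "uniprot_accession": up_acc,
            "genpept_accession": gp_acc,
        },
        "db_feature_counts": {
            "uniprot": len(up_features),
            # GenPept: the `source` feature is skipped by the parser
            "genpept": len(gp_features) - 1,
        },
        "files": files,
        "iupred_runs": [list(r) for r in iupred_runs],
        "anchor_runs": [list(r) for r in anchor_runs],
        "table_rows": len(rows),
    }
    _write(out / "manifest.json",
           json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest


def random_scheme(
    rng: random.Random,
    vocabulary=None,
    max_length: int = 1500,
) -> ProteinScheme:
    """A random valid scheme: random length, regions with occasionally
    shared labels, motifs and markups drawn from the full vocabulary."""
    vocab = vocabulary or default_vocabulary()
    length = rng.randint(60, max_length)
    features: list[FeatureRecord] = []
    labels = rng.sample(_REGION_LABELS, k=rng.randint(1, 4))
    for _ in range(rng.randint(0, 5)):
        start = rng.randint(1, max(1, length - 30))
        end = min(length, start + rng.randint(10, 400))
        type_key = rng.choice(vocab.type_keys(Category.REGION))
        features.append(
            FeatureRecord(
                category=Category.REGION,
                type_key=type_key,
                label=rng.choice(labels),
                start=start,
                end=end,
                is_repeat=(type_key == "repeat"),
                score=None,
                source=rng.choice(list(Source)),
            )
        )
    motif_keys = vocab.type_keys(Category.MOTIF)
    for _ in range(rng.randint(0, 6)):
        start = rng.randint(1, max(1, length - 5))
        end = min(length, start + rng.randint(1, 40))
        key = rng.choice(motif_keys)
        features.append(
            FeatureRecord(
                category=Category.MOTIF,
                type_key=key,
                label=vocab.display_name(Category.MOTIF, key),
                start=start,
                end=end,
                score=rng.choice([None, round(rng.uniform(0, 1), 3)]),
                source=rng.choice(list(Source)),
            )
        )
    markup_keys = vocab.type_keys(Category.MARKUP)
    for _ in range(rng.randint(0, 10)):
        pos = rng.randint(1, length)
        key = rng.choice(markup_keys)
        features.append(
            FeatureRecord(
                category=Category.MARKUP,
                type_key=key,
                label=vocab.display_name(Category.MARKUP, key),
                start=pos,
                end=pos,
                score=rng.choice([None, round(rng.uniform(0, 1), 3)]),
                source=rng.choice(list(Source)),
            )
        )
    return ProteinScheme.assemble(
        name=f"RND{rng.randint(1, 999)}",
        length=length,
        accession=None,
        features=features,
        vocabulary=vocab,
    )


def main(argv=None) -> int:  # pragma: no cover - thin wrapper
    import argparse

    ap = argparse.ArgumentParser(description="Generate synthetic test fixtures")
    ap.add_argument("out_dir")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args(argv)
    manifest = generate_fixtures(args.seed, args.out_dir)
    print(json.dumps({"length": manifest["protein"]["length"],
                      "files": sorted(manifest["files"])}, indent=2))
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
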