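"""Input readers: database records, prediction-server outputs, feature tables.

Three ways of supplying protein feature evidence are supported, mirroring
the three input modes of the CLI:

1. **Database records** — UniProt entries (JSON preferred, flat text as
   fallback) and NCBI GenPept flat files, identified by accession.
2. **Raw prediction results** — the saved text output of seven servers:
   SMART (domains), ELM (short linear motifs), NetNGlyc / NetOGlyc /
   NetPhos / ScanSite (single-site PTM predictions) and IUPred/ANCHOR
   (per-residue disorder scores, segmented into intervals here). Server
   output formats drift between versions, so each dialect is pinned to
   the format documented in ``docs/formats.md`` (dialect version 1) and
   exemplified by the generated fixtures.
3. **Curated tables** — user-prepared xlsx/csv/tsv tables of features.

All readers emit :class:`RawFeature` lists (pre-classification) except
:func:`read_feature_table`, which classifies rows on the fly (or passes
them through when the row carries an explicit category).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .feature_model import (
    Category,
    CoordinateError,
    FeatureRecord,
    SchemeError,
    Source,
    VocabularyError,
)

__all__ = [
    "RawFeature",
    "CutoffConfig",
    "DEFAULT_CUTOFFS",
    "RetrievalError",
    "DialectError",
    "TableSchemaError",
    "RecordParseError",
    "fetch_record",
    "parse_db_record",
    "parse_prediction_output",
    "read_feature_table",
    "PREDICTION_SOURCES",
    "DIALECT_VERSION",
]

#: Version tag of the raw-format dialects accepted by the parsers below.
DIALECT_VERSION = "1"

PREDICTION_SOURCES = (
    Source.SMART,
    Source.ELM,
    Source.NETNGLYC,
    Source.NETOGLYC,
    Source.NETPHOS,
    Source.SCANSITE,
    Source.IUPRED_ANCHOR,
)


class RetrievalError(SchemeError):
    """A database record could not be fetched or located."""


class DialectError(SchemeError):
    """Input text is not in the expected resource dialect."""


class TableSchemaError(SchemeError):
    """A curated feature table is missing a required column."""


class RecordParseError(SchemeError):
    """A database record could not be parsed."""


@dataclass(frozen=True)
class RawFeature:
    """One pre-classification feature: a source-native key plus coordinates."""

    keyword: str
    start: int
    end: int
    score: Optional[float] = None
    source: Source = Source.CUSTOM

    def __post_init__(self) -> None:
        if not self.keyword:
            raise ValueError("RawFeature keyword must be non-empty")
        if self.start > self.end:
            raise CoordinateError(
                f"inverted interval {self.start}..{self.end} for {self.keyword!r}"
            )


# Default decision thresholds. The site predictors and the disorder
# predictors all report a [0, 1] propensity for which 0.5 is the
# conventional decision boundary; SMART rows are filtered by e-value only
# when a ceiling is configured; ScanSite results are passed through
# unfiltered (its stringency is chosen on the server).
DEFAULT_CUTOFFS: dict[str, Optional[float]] = {
    "smart": None,
    "elm": None,
    "netnglyc": 0.5,
    "netoglyc": 0.5,
    "netphos": 0.5,
    "scansite": None,
    "iupred": 0.5,
    "anchor": 0.5,
}


@dataclass
class CutoffConfig:
    """Per-resource score thresholds.

    Keys are resource names (``netphos``, ``iupred``, ``anchor``, ...).
    ``None`` disables filtering for that resource. For SMART the value is
    an e-value ceiling (rows *above* it are dropped); everywhere else it
    is a score floor (rows *below* it are dropped).
    """

    thresholds: dict[str, Optional[float]] = field(default_factory=dict)

    def get(self, name: str) -> Optional[float]:
        value = self.thresholds.get(name, DEFAULT_CUTOFFS.get(name))
        if value is not None and not math.isfinite(value):
            raise ValueError(f"cutoff for {name!r} must be finite, got {value}")
        return value


_UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.json"
_GENPEPT_URL = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=protein&id={acc}&rettype=gp&retmode=text"
)
_FIXTURE_SUFFIXES = (".json", ".txt", ".dat", ".gp", ".gb", ".genpept")


def fetch_record(
    accession: str,
    database: Union[str, Source],
    offline_fixture: Optional[Union[str, Path]] = None,
    cache_dir: Optional[Union[str, Path]] = None,
) -> str:
    """Return the raw text of a database record.

    With ``offline_fixture`` (a record file, or a directory searched for
    ``<accession>.*``) no network is touched. Live fetches go to the
    UniProt REST API or NCBI efetch and are cached in ``cache_dir`` keyed
    by (database, accession).
    """
    database = Source(database)
    if database not in (Source.UNIPROT, Source.GENPEPT):
        raise ValueError(f"unsupported database {database}")
    if not accession:
        raise RetrievalError(f"empty accession for database {database}")

    if offline_fixture is not None:
        path = Path(offline_fixture)
        if path.is_dir():
            candidates = [
                p
                for p in sorted(path.iterdir())
                if p.name.startswith(accession) and p.suffix in _FIXTURE_SUFFIXES
            ]
            if not candidates:
                raise RetrievalError(
                    f"no fixture for {database} accession {accession!r} in {path}"
                )
            path = candidates[0]
        if not path.exists():
            raise RetrievalError(f"fixture {path} does not exist")
        return path.read_text(encoding="utf-8")

    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"{database.value}_{accession}.txt"
        if cache_path.exists():
            return cache_path.read_text(encoding="utf-8")

    url = (_UNIPROT_URL if database is Source.UNIPROT else _GENPEPT_URL).format(
        acc=accession
    )
    try:
        from urllib.request import urlopen

        with urlopen(url, timeout=30) as resp:  # pragma: no cover - needs network
            text = resp.read().decode("utf-8")
    except Exception as exc:
        raise RetrievalError(
            f"could not retrieve {database} record {accession!r}: {exc}"
        ) from exc
    if cache_path is not None:  # pragma: no cover - needs network
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        cache_path.write_text(text, encoding="utf-8")
    return text  # pragma: no cover - needs network


# ---------------------------------------------------------------------------
# database record parsing
# ---------------------------------------------------------------------------


def _pair_sites(keyword: str, start: int, end: int, source: Source) -> list[RawFeature]:
    """Bond-type annotations (disulfide bridges, isopeptide cross-links)
    span the two partner residues in database records; the scheme shows a
    lollipop at each partner instead."""
    if start == end:
        return [RawFeature(keyword, start, start, source=source)]
    return [
        RawFeature(keyword, start, start, source=source),
        RawFeature(keyword, end, end, source=source),
    ]


_BOND_KEYS = ("disulfid", "crosslnk", "cross-link", "isopeptide")

# whole-protein bookkeeping entries that carry no topology information
_SKIPPED_UNIPROT_TYPES = frozenset({"chain", "sequence conflict", "natural variant",
                                    "mutagenesis", "alternative sequence"})


def _feature_keyword(ftype: str, description: str) -> str:
    if description and description.lower() != ftype.lower():
        return f"{ftype}: {description}" if ftype else description
    return ftype or description


def _parse_uniprot_json(text: str) -> tuple[str, int, list[RawFeature]]:
    doc = json.loads(text)
    try:
        length = int(doc["sequence"]["length"])
    except (KeyError, TypeError) as exc:
        raise RecordParseError("UniProt record lacks sequence length") from exc
    name = doc.get("accession") or doc.get("primaryAccession", "")
    try:
        name = doc["proteinDescription"]["recommendedName"]["fullName"]["value"]
    except (KeyError, TypeError):
        pass
    raws: list[RawFeature] = []
    for feat in doc.get("features", []):
        ftype = feat.get("type", "")
        if ftype.lower() in _SKIPPED_UNIPROT_TYPES:
            continue
        desc = feat.get("description", "") or ""
        loc = feat.get("location", {})
        try:
            start = int(loc["start"]["value"])
            end = int(loc["end"]["value"])
        except (KeyError, TypeError, ValueError):
            continue  # positionally unresolved feature
        keyword = _feature_keyword(ftype, desc)
        if any(b in keyword.lower() for b in _BOND_KEYS) or "disulfide" in ftype.lower():
            raws.extend(_pair_sites(keyword, start, end, Source.UNIPROT))
        else:
            raws.append(RawFeature(keyword, start, end, source=Source.UNIPROT))
    return name, length, raws


_FT_LINE = re.compile(r"^FT   (\S+)\s+(\d+)(?:\.\.(\d+))?\s*$")
_FT_NOTE = re.compile(r'^FT\s+/note="([^"]*)"?')


def _parse_uniprot_flat(text: str) -> tuple[str, int, list[RawFeature]]:
    """Fallback reader for the UniProt flat-text form.

    Only the ID line (length), DE RecName and FT table are consumed; this
    is intentionally a small line reader because full SwissProt parsing
    requires complete records.
    """
    name = ""
    length = None
    entries: list[list] = []  # [key, start, end, note]
    for line in text.splitlines():
        if line.startswith("ID   "):
            m = re.search(r"(\d+)\s+AA", line)
            if m:
                length = int(m.group(1))
        elif line.startswith("DE   RecName:") and not name:
            m = re.search(r"Full=([^;{]+)", line)
            if m:
                name = m.group(1).strip()
        elif line.startswith("FT   "):
            m = _FT_LINE.match(line)
            if m:
                key, s, e = m.group(1), int(m.group(2)), m.group(3)
                entries.append([key, s, int(e) if e else s, ""])
            else:
                m = _FT_NOTE.match(line)
                if m and entries:
                    entries[-1][3] = m.group(1)
    if length is None:
        raise RecordParseError("UniProt flat record lacks an ID line with length")
    raws: list[RawFeature] = []
    for key, start, end, note in entries:
        if key.upper() in ("CHAIN", "VARIANT", "MUTAGEN", "CONFLICT", "VAR_SEQ"):
            continue
        keyword = _feature_keyword(key, note)
        if key.upper() in ("DISULFID", "CROSSLNK"):
            raws.extend(_pair_sites(keyword, start, end, Source.UNIPROT))
        else:
            raws.append(RawFeature(keyword, start, end, source=Source.UNIPROT))
    return name, length, raws


def _parse_genpept(text: str) -> tuple[str, int, list[RawFeature]]:
    from Bio import SeqIO

    try:
        record = SeqIO.read(StringIO(text), "genbank")
    except ValueError as exc:
        raise RecordParseError(f"not a parseable GenPept record: {exc}") from exc
    length = len(record.seq)
    if length == 0:
        raise RecordParseError("GenPept record has no sequence length")
    name = record.description or record.id
    raws: list[RawFeature] = []
    for feat in record.features:
        if feat.type in ("source",):
            continue
        quals = feat.qualifiers
        desc_parts = [
            quals.get("region_name", [""])[0],
            quals.get("site_type", [""])[0],
            quals.get("note", [""])[0],
        ]
        desc = " ".join(p for p in desc_parts if p)
        keyword = _feature_keyword(feat.type, desc)
        start = int(feat.location.start) + 1  # 0-based half-open -> 1-based
        end = int(feat.location.end)
        if any(b in keyword.lower() for b in _BOND_KEYS):
            raws.extend(_pair_sites(keyword, start, end, Source.GENPEPT))
        else:
            raws.append(RawFeature(keyword, start, end, source=Source.GENPEPT))
    return name, length, raws


def parse_db_record(
    text: str,
    database: Union[str, Source],
    selected: Optional[Iterable[Union[str, Category]]] = None,
    vocabulary=None,
) -> tuple[str, int, list[RawFeature]]:
    """Parse a database record into (protein name, length, raw features).

    ``selected`` restricts the output to feature keys classifying into the
    given categories (all three by default). UniProt records may be JSON
    (preferred) or flat text; GenPept records are GenBank-dialect flat
    files.
    """
    database = Source(database)
    if database is Source.UNIPROT:
        if text.lstrip().startswith("{"):
            name, length, raws = _parse_uniprot_json(text)
        else:
            name, length, raws = _parse_uniprot_flat(text)
    elif database is Source.GENPEPT:
        name, length, raws = _parse_genpept(text)
    else:
        raise DialectError(f"unknown database dialect {database}")

    raws = [r for r in raws if 1 <= r.start <= r.end <= length]
    if selected is not None:
        from .classify import default_vocabulary

        vocab = vocabulary or default_vocabulary()
        wanted = {Category(c) for c in selected}
        kept = []
        for r in raws:
            hit = vocab.match(r.keyword, is_site=(r.start == r.end))
            category = (
                hit[0]
                if hit
                else (Category.MARKUP if r.start == r.end else Category.MOTIF)
            )
            if category in wanted:
                kept.append(r)
        raws = kept
    return name, length, raws


# ---------------------------------------------------------------------------
# prediction-server output parsing (dialect version 1, see docs/formats.md)
# ---------------------------------------------------------------------------

_RESIDUE_NAMES = {"S": "serine", "T": "threonine", "Y": "tyrosine"}


def _data_lines(text: str) -> list[str]:
    return [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]


def _check_pos(pos: int, protein_length: int, row: str) -> None:
    if pos < 1 or pos > protein_length:
        raise CoordinateError(
            f"position {pos} outside protein of length {protein_length} "
            f"in row: {row!r}"
        )


def _parse_smart(lines, cutoff, protein_length):
    raws = []
    for ln in lines:
        fields = dict(tok.split("=", 1) for tok in ln.split() if "=" in tok)
        try:
            name, start, end = fields["name"], int(fields["start"]), int(fields["end"])
        except (KeyError, ValueError) as exc:
            raise DialectError(f"bad SMART row: {ln!r}") from exc
        evalue = float(fields["evalue"]) if "evalue" in fields else None
        _check_pos(start, protein_length, ln)
        _check_pos(end, protein_length, ln)
        if cutoff is not None and evalue is not None and evalue > cutoff:
            continue
        raws.append(
            RawFeature(f"{name} domain", start, end, score=evalue, source=Source.SMART)
        )
    return raws


def _parse_elm(lines, cutoff, protein_length):
    raws = []
    for ln in lines:
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if parts[0].lower().startswith("elm_identifier"):
            continue  # header
        try:
            ident, start, stop = parts[0], int(parts[1]), int(parts[2])
        except (IndexError, ValueError) as exc:
            raise DialectError(f"bad ELM row: {ln!r}") from exc
        score = float(parts[3]) if len(parts) > 3 else None
        _check_pos(start, protein_length, ln)
        _check_pos(stop, protein_length, ln)
        if cutoff is not None and score is not None and score < cutoff:
            continue
        raws.append(RawFeature(ident, start, stop, score=score, source=Source.ELM))
    return raws


def _parse_netnglyc(lines, cutoff, protein_length):
    raws = []
    for ln in lines:
        parts = ln.split()
        if len(parts) < 4:
            raise DialectError(f"bad NetNGlyc row: {ln!r}")
        try:
            pos, sequon, potential = int(parts[1]), parts[2], float(parts[3])
        except ValueError as exc:
            raise DialectError(f"bad NetNGlyc row: {ln!r}") from exc
        _check_pos(pos, protein_length, ln)
        if cutoff is not None and potential < cutoff:
            continue
        raws.append(
            RawFeature(
                f"N-glycosylation ({sequon})",
                pos,
                pos,
                score=potential,
                source=Source.NETNGLYC,
            )
        )
    return raws


def _parse_netoglyc(lines, cutoff, protein_length):
    raws = []
    for ln in lines:
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) < 6:
            raise DialectError(f"bad NetOGlyc row: {ln!r}")
        try:
            start, end, score = int(parts[3]), int(parts[4]), float(parts[5])
        except ValueError as exc:
            raise DialectError(f"bad NetOGlyc row: {ln!r}") from exc
        _check_pos(start, protein_length, ln)
        if cutoff is not None and score < cutoff:
            continue
        raws.append(
            RawFeature(
                "O-glycosylation", start, start, score=score, source=Source.NETOGLYC
            )
        )
    return raws


def _parse_netphos(lines, cutoff, protein_length):
    raws = []
    for ln in lines:
        parts = ln.split()
        if len(parts) < 5:
            raise DialectError(f"bad NetPhos row: {ln!r}")
        try:
            pos, residue, score = int(parts[1]), parts[2].upper(), float(parts[4])
        except ValueError as exc:
            raise DialectError(f"bad NetPhos row: {ln!r}") from exc
        kinase = parts[5] if len(parts) > 5 else ""
        _check_pos(pos, protein_length, ln)
        if cutoff is not None and score < cutoff:
            continue
        resname = _RESIDUE_NAMES.get(residue, "site")
        label = f"Phospho-{resname}" if resname != "site" else "Phosphorylation"
        if kinase:
            label += f" ({kinase})"
        raws.append(RawFeature(label, pos, pos, score=score, source=Source.NETPHOS))
    return raws


_SCANSITE_SITE = re.compile(r"^([A-Z])(\d+)$")


def _parse_scansite(lines, cutoff, protein_length):
    raws = []
    for ln in lines:
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) < 4:
            raise DialectError(f"bad ScanSite row: {ln!r}")
        motif_name, site = parts[1], parts[2]
        m = _SCANSITE_SITE.match(site)
        if m is None:
            raise DialectError(f"bad ScanSite site field in row: {ln!r}")
        residue, pos = m.group(1), int(m.group(2))
        try:
            score = float(parts[3])
        except ValueError as exc:
            raise DialectError(f"bad ScanSite row: {ln!r}") from exc
        _check_pos(pos, protein_length, ln)
        resname = _RESIDUE_NAMES.get(residue)
        if resname is not None:
            keyword = f"Phospho-{resname} ({motif_name})"
        else:
            keyword = motif_name
        raws.append(RawFeature(keyword, pos, pos, score=score, source=Source.SCANSITE))
    return raws


def _segment_runs(scores: Sequence[tuple[int, float]], cutoff: float):
    """Maximal runs of consecutive residues with score >= cutoff."""
    runs = []
    run_start = None
    run_scores: list[float] = []
    prev_pos = None
    for pos, score in scores:
        above = score >= cutoff
        contiguous = prev_pos is not None and pos == prev_pos + 1
        if above and run_start is not None and contiguous:
            run_scores.append(score)
        elif above:
            if run_start is not None:
                runs.append((run_start, prev_pos, run_scores))
            run_start, run_scores = pos, [score]
        elif run_start is not None:
            runs.append((run_start, prev_pos, run_scores))
            run_start, run_scores = None, []
        prev_pos = pos
    if run_start is not None:
        runs.append((run_start, prev_pos, run_scores))
    return [(s, e, sum(sc) / len(sc)) for s, e, sc in runs]


def _parse_iupred_anchor(lines, cutoffs: CutoffConfig, protein_length):
    iupred: list[tuple[int, float]] = []
    anchor: list[tuple[int, float]] = []
    for ln in lines:
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) < 3:
            raise DialectError(f"bad IUPred/ANCHOR row: {ln!r}")
        try:
            pos = int(parts[0])
            iup = float(parts[2])
        except ValueError as exc:
            raise DialectError(f"bad IUPred/ANCHOR row: {ln!r}") from exc
        _check_pos(pos, protein_length, ln)
        iupred.append((pos, iup))
        if len(parts) > 3:
            anchor.append((pos, float(parts[3])))
    raws = []
    iup_cut = cutoffs.get("iupred")
    anc_cut = cutoffs.get("anchor")
    if iup_cut is not None:
        for start, end, mean in _segment_runs(iupred, iup_cut):
            raws.append(
                RawFeature(
                    "Intrinsic disorder",
                    start,
                    end,
                    score=round(mean, 4),
                    source=Source.IUPRED_ANCHOR,
                )
            )
    if anc_cut is not None:
        for start, end, mean in _segment_runs(anchor, anc_cut):
            raws.append(
                RawFeature(
                    "Disordered binding (ANCHOR)",
                    start,
                    end,
                    score=round(mean, 4),
                    source=Source.IUPRED_ANCHOR,
                )
            )
    return raws


def parse_prediction_output(
    text: str,
    source: Union[str, Source],
    cutoffs: Optional[CutoffConfig] = None,
    protein_length: int = 10**9,
) -> list[RawFeature]:
    """Parse one saved prediction-server output into raw features.

    Rows scoring below the resource's cutoff (above, for SMART e-values)
    are dropped. IUPred/ANCHOR per-residue scores are segmented into
    maximal runs of consecutive residues at-or-above the cutoff, emitted
    as disorder (IUPred column) and disordered-binding (ANCHOR column)
    intervals. Site predictors emit single-residue features; SMART emits
    domain intervals; ELM emits motif intervals.
    """
    source = Source(source)
    if source not in PREDICTION_SOURCES:
        raise DialectError(f"unsupported prediction source {source}")
    cutoffs = cutoffs or CutoffConfig()
    lines = _data_lines(text)
    if not lines:
        return []
    if source is Source.SMART:
        return _parse_smart(lines, cutoffs.get("smart"), protein_length)
    if source is Source.ELM:
        return _parse_elm(lines, cutoffs.get("elm"), protein_length)
    if source is Source.NETNGLYC:
        return _parse_netnglyc(lines, cutoffs.get("netnglyc"), protein_length)
    if source is Source.NETOGLYC:
        return _parse_netoglyc(lines, cutoffs.get("netoglyc"), protein_length)
    if source is Source.NETPHOS:
        return _parse_netphos(lines, cutoffs.get("netphos"), protein_length)
    if source is Source.SCANSITE:
        return _parse_scansite(lines, cutoffs.get("scansite"), protein_length)
    return _parse_iupred_anchor(lines, cutoffs, protein_length)


# ---------------------------------------------------------------------------
# curated feature tables
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("name", "type", "start", "end")
OPTIONAL_COLUMNS = ("category", "colour", "source", "score", "is_repeat")

_FORMAT_SEPS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "xlsx"):
        return suffix
    raise ValueError(f"cannot infer table format from suffix of {path.name!r}")


def _read_metadata_lines(path: Path) -> dict[str, str]:
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*([\w ]+)\s*:\s*(.+)", line)
            if m:
                meta[m.group(1).strip().lower()] = m.group(2).strip()
    return meta


def read_feature_table(
    path: Union[str, Path],
    format: Optional[str] = None,
    vocabulary=None,
) -> tuple[dict, list[FeatureRecord]]:
    """Read a curated feature table (csv/tsv/xlsx).

    Required columns: ``name, type, start, end``; optional: ``category,
    colour, source, score, is_repeat``. Rows carrying an explicit category
    are passed through classification-free (an invalid type key then hard
    fails); rows without one have their ``type`` keyword classified.

    csv/tsv files may start with ``# key: value`` comment lines; these are
    returned in the metadata dict (conventional keys: ``protein``,
    ``length``, ``accession``). Per-row colour overrides are collected
    under metadata key ``colours`` (label -> colour).
    """
    from .classify import classify_feature, default_vocabulary

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or _infer_format(path)).lower()
    metadata: dict = {}
    if fmt in _FORMAT_SEPS:
        metadata.update(_read_metadata_lines(path))
        # leading '#' lines are metadata; '#' elsewhere (colours) is data
        with open(path, "r", encoding="utf-8") as fh:
            n_comment = 0
            for line in fh:
                if not line.startswith("#"):
                    break
                n_comment += 1
        df = pd.read_csv(path, sep=_FORMAT_SEPS[fmt], skiprows=n_comment,
                         dtype=str)
    elif fmt == "xlsx":
        df = pd.read_excel(path, dtype=str)
    else:
        raise ValueError(f"unsupported table format {fmt!r}")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TableSchemaError(f"feature table is missing required column {col!r}")

    vocab = vocabulary or default_vocabulary()
    records: list[FeatureRecord] = []
    colours: dict[str, str] = {}
    for idx, row in df.iterrows():
        rownum = idx + 2  # 1-based, after the header row
        name = "" if pd.isna(row["name"]) else str(row["name"]).strip()
        type_field = "" if pd.isna(row["type"]) else str(row["type"]).strip()
        try:
            start = int(str(row["start"]).strip())
            end = int(str(row["end"]).strip())
        except (TypeError, ValueError):
            raise ValueError(
                f"non-integer coordinate in table row {rownum}: "
                f"start={row['start']!r} end={row['end']!r}"
            ) from None
        score = None
        if "score" in df.columns and not pd.isna(row["score"]):
            score = float(row["score"])
        source = Source.CUSTOM
        if "source" in df.columns and not pd.isna(row["source"]):
            source = Source(str(row["source"]).strip().lower())
        is_repeat = False
        if "is_repeat" in df.columns and not pd.isna(row["is_repeat"]):
            is_repeat = str(row["is_repeat"]).strip().lower() in ("1", "true", "yes")

        category = None
        if "category" in df.columns and not pd.isna(row["category"]):
            category = str(row["category"]).strip().lower()
        if category:
            cat = Category(category)
            if not vocab.has_type(cat, type_field):
                raise VocabularyError(
                    f"row {rownum}: unknown type key {type_field!r} for "
                    f"category {cat}"
                )
            rec = FeatureRecord(
                category=cat,
                type_key=type_field,
                label=name or vocab.display_name(cat, type_field),
                start=start,
                end=end,
                is_repeat=is_repeat,
                score=score,
                source=source,
            )
        else:
            raw = RawFeature(type_field, start, end, score=score, source=source)
            rec = classify_feature(raw, vocab)
            if name:
                rec = rec.replace(label=name)
            if is_repeat and rec.category is Category.REGION:
                rec = rec.replace(is_repeat=True)
        if "colour" in df.columns and not pd.isna(row["colour"]):
            colours[rec.label] = str(row["colour"]).strip()
        records.append(rec)
    if colours:
        metadata["colours"] = colours
    return metadata, records
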