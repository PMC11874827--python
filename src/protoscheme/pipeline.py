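"""High-level pipelines: from any accepted input to a finished scheme."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .classify import classify_feature, deduplicate, default_vocabulary
from .feature_model import Category, ProteinScheme, Source
from .ingest import (
    CutoffConfig,
    RawFeature,
    fetch_record,
    parse_db_record,
    parse_prediction_output,
    read_feature_table,
)

__all__ = [
    "build_scheme",
    "scheme_from_record",
    "scheme_from_predictions",
    "scheme_from_table",
]


def build_scheme(
    name: str,
    length: int,
    raw_features: Iterable[RawFeature],
    accession: Optional[str] = None,
    vocabulary=None,
    drop_duplicates: bool = True,
) -> ProteinScheme:
    """Classify raw features and assemble a validated, sorted scheme.

    Duplicate annotations arriving from several resources are collapsed
    (source precedence UniProt > GenPept > predictors) unless
    ``drop_duplicates`` is disabled.
    """
    vocab = vocabulary or default_vocabulary()
    records = [classify_feature(r, vocab) for r in raw_features]
    if drop_duplicates:
        records = deduplicate(records)
    return ProteinScheme.assemble(
        name=name, length=length, accession=accession, features=records,
        vocabulary=vocab,
    )


def scheme_from_record(
    accession: str,
    database: Union[str, Source] = Source.UNIPROT,
    offline_fixture: Optional[Union[str, Path]] = None,
    categories: Optional[Iterable[Union[str, Category]]] = None,
    cache_dir: Optional[Union[str, Path]] = None,
    vocabulary=None,
) -> ProteinScheme:
    """Scheme straight from a UniProt or GenPept accession."""
    text = fetch_record(accession, database, offline_fixture, cache_dir)
    name, length, raws = parse_db_record(
        text, database, selected=categories, vocabulary=vocabulary
    )
    return build_scheme(
        name or accession, length, raws, accession=accession,
        vocabulary=vocabulary,
    )


def scheme_from_predictions(
    inputs: Mapping[Union[str, Source], str],
    length: int,
    name: str = "protein",
    cutoffs: Optional[CutoffConfig] = None,
    accession: Optional[str] = None,
    vocabulary=None,
) -> ProteinScheme:
    """Scheme from raw prediction-server outputs.

    ``inputs`` maps a prediction source to the saved raw text of that
    server's result for the protein.
    """
    raws: list[RawFeature] = []
    for source, text in inputs.items():
        raws.extend(
            parse_prediction_output(text, source, cutoffs, protein_length=length)
        )
    return build_scheme(name, length, raws, accession=accession,
                        vocabulary=vocabulary)


def scheme_from_table(
    path: Union[str, Path],
    name: Optional[str] = None,
    length: Optional[int] = None,
    format: Optional[str] = None,
    vocabulary=None,
) -> ProteinScheme:
    """Scheme from a curated feature table.

    Protein name and length come from the arguments, falling back to the
    table's ``# protein`` / ``# length`` metadata lines; as a last resort
    the length is the largest feature end coordinate.
    """
    metadata, records = read_feature_table(path, format=format,
                                           vocabulary=vocabulary)
    if name is None:
        name = metadata.get("protein") or metadata.get("name") or Path(path).stem
    if length is None and "length" in metadata:
        length = int(metadata["length"])
    if length is None:
        if not records:
            raise ValueError("cannot infer protein length from an empty table")
        length = max(r.end for r in records)
    scheme = ProteinScheme.assemble(
        name=name, length=length,
        accession=metadata.get("accession"), features=records,
        vocabulary=vocabulary or default_vocabulary(),
    )
    return scheme
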