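"""Core domain types for protein topology schemes.

A protein topology scheme is a linear diagram of a protein: *regions*
(domains, repeats — long intervals drawn as shaped boxes), *motifs*
(short linear intervals such as signal peptides, transmembrane segments
or disorder stretches, drawn as coloured bars) and *markups*
(single-residue annotations such as PTMs, drawn as lollipops).

All coordinates are 1-based and inclusive on both ends, following the
UniProt/GenPept feature-table convention. Markups are stored with
``start == end`` so the three categories share one record type.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "Category",
    "Source",
    "FeatureRecord",
    "ProteinScheme",
    "RenderOptions",
    "SchemeError",
    "CoordinateError",
    "CategoryError",
    "VocabularyError",
    "validate_feature",
    "sort_features",
]


class SchemeError(Exception):
    """Base class for all scheme-construction errors."""


class CoordinateError(SchemeError):
    """A feature's coordinates fall outside the protein or are inverted."""


class CategoryError(SchemeError):
    """A feature violates a category-specific constraint."""


class VocabularyError(SchemeError):
    """A type key is not present in the controlled vocabulary."""


class Category(str, enum.Enum):
    """The three feature categories of a topology scheme."""

    REGION = "region"
    MOTIF = "motif"
    MARKUP = "markup"

    def __str__(self) -> str:  # serialize as the bare value
        return self.value


#: Sort rank used to break ties between co-located features: regions are
#: drawn first (bottom layer), then motifs, then markups on top.
_CATEGORY_RANK = {Category.REGION: 0, Category.MOTIF: 1, Category.MARKUP: 2}


class Source(str, enum.Enum):
    """Provenance of a feature annotation."""

    UNIPROT = "uniprot"
    GENPEPT = "genpept"
    SMART = "smart"
    ELM = "elm"
    NETNGLYC = "netnglyc"
    NETOGLYC = "netoglyc"
    NETPHOS = "netphos"
    SCANSITE = "scansite"
    IUPRED_ANCHOR = "iupred_anchor"
    CUSTOM = "custom"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class FeatureRecord:
    """One classified feature: an annotated interval or site on a protein.

    Parameters
    ----------
    category
        One of :class:`Category`.
    type_key
        Canonical vocabulary identifier (e.g. ``signal_peptide``,
        ``n_glycosylation``). Must exist in the vocabulary for its category.
    label
        Free-text display name shown in the scheme and legend.
    start, end
        1-based inclusive residue indices; markups require ``start == end``.
    is_repeat
        Regions only: draw with jagged (repeat) ends.
    score
        Optional prediction confidence, unitless.
    source
        Provenance (:class:`Source`).
    """

    category: Category
    type_key: str
    label: str
    start: int
    end: int
    is_repeat: bool = False
    score: Optional[float] = None
    source: Source = Source.CUSTOM

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "source", Source(self.source))
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def replace(self, **changes) -> "FeatureRecord":
        return replace(self, **changes)


def validate_feature(
    feature: FeatureRecord,
    protein_length: int,
    vocabulary=None,
) -> FeatureRecord:
    """Check a feature's invariants against a protein of the given length.

    Returns the feature unchanged when valid. Validation is idempotent.

    Raises
    ------
    CoordinateError
        If coordinates are inverted or fall outside ``1..protein_length``.
    CategoryError
        If a markup spans more than one residue, or ``is_repeat`` is set on
        a non-region.
    VocabularyError
        If a vocabulary is supplied and the type key is unknown for the
        feature's category.
    """
    if protein_length < 1:
        raise ValueError(f"protein length must be >= 1, got {protein_length}")
    f = feature
    if not (1 <= f.start <= f.end <= protein_length):
        raise CoordinateError(
            f"feature {f.label!r} ({f.type_key}) at {f.start}..{f.end} is out of "
            f"bounds for a protein of length {protein_length}"
        )
    if f.category is Category.MARKUP and f.start != f.end:
        raise CategoryError(
            f"markup {f.label!r} must be a single site, got {f.start}..{f.end}"
        )
    if f.is_repeat and f.category is not Category.REGION:
        raise CategoryError(
            f"is_repeat is only meaningful for regions; {f.label!r} is {f.category}"
        )
    if vocabulary is not None and not vocabulary.has_type(f.category, f.type_key):
        raise VocabularyError(
            f"unknown type key {f.type_key!r} for category {f.category}"
        )
    return f


def sort_features(features: Iterable[FeatureRecord]) -> list[FeatureRecord]:
    """Stable sort by (start, end, category rank region<motif<markup).

    Features with identical keys keep their input order, so the result is
    a permutation of the input.
    """
    return sorted(
        features, key=lambda f: (f.start, f.end, _CATEGORY_RANK[f.category])
    )


@dataclass
class ProteinScheme:
    """A protein plus its classified features — the unit that is encoded,
    decoded and rendered.

    ``length`` is the protein length in amino acids; the sequence itself is
    never stored. ``features`` are kept sorted by (start, end, category)
    after assembly.
    """

    name: str
    length: int
    accession: Optional[str] = None
    features: list[FeatureRecord] = field(default_factory=list)

    @classmethod
    def assemble(
        cls,
        name: str,
        length: int,
        features: Sequence[FeatureRecord],
        accession: Optional[str] = None,
        vocabulary=None,
    ) -> "ProteinScheme":
        """Validate every feature against ``length`` and return a sorted scheme."""
        if length < 1:
            raise ValueError(f"protein length must be >= 1, got {length}")
        validated = [validate_feature(f, length, vocabulary) for f in features]
        return cls(
            name=name,
            length=int(length),
            accession=accession,
            features=sort_features(validated),
        )

    def validate(self, vocabulary=None) -> "ProteinScheme":
        for f in self.features:
            validate_feature(f, self.length, vocabulary)
        return self

    def by_category(self, category: Category) -> list[FeatureRecord]:
        category = Category(category)
        return [f for f in self.features if f.category is category]


@dataclass(frozen=True)
class RenderOptions:
    """Rendering knobs: amino-acid pixel size, proportional rescale factor,
    motif opacity and palette choice.

    ``px_per_aa`` sets how many horizontal SVG units one residue occupies
    (zooming the scheme by stretching it); ``rescale`` scales the whole
    drawing proportionally; ``motif_opacity`` is the fill opacity of motif
    bars in ``[0, 1]``.
    """

    px_per_aa: float = 1.0
    rescale: float = 1.0
    motif_opacity: float = 0.8
    palette: str = "rainbow"

    def __post_init__(self) -> None:
        if self.px_per_aa <= 0:
            raise ValueError(f"px_per_aa must be > 0, got {self.px_per_aa}")
        if self.rescale <= 0:
            raise ValueError(f"rescale must be > 0, got {self.rescale}")
        if not (0.0 <= self.motif_opacity <= 1.0):
            raise ValueError(
                f"motif_opacity must be in [0, 1], got {self.motif_opacity}"
            )
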