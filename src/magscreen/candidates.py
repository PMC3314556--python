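"""Function-based candidate selection: keyword and homology searches.

Candidates enter the screen either because their annotated product string
matches a functional-class keyword (electron transport / complex I,
sodium transport, ABC transport, channels and pores) or because they
align to a seed protein already linked to marine adaptation (complex I
subunits, MscL). The default keyword lists are a documented stand-in
covering the four classes with standard product-name vocabulary; callers
can supply their own.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .orthologs import ProteinRecord, ScreenConfig, align_pair

__all__ = [
    "FunctionalClass",
    "KeywordSet",
    "DEFAULT_KEYWORDS",
    "keyword_candidates",
    "homology_candidates",
    "load_keywords",
]

logger = logging.getLogger(__name__)


class FunctionalClass(str, enum.Enum):
    ETS_COMPLEX_I = "ets_complex_i"
    NA_TRANSPORT = "na_transport"
    ABC_TRANSPORT = "abc_transport"
    CHANNELS_PORES = "channels_pores"


@dataclass(frozen=True)
class KeywordSet:
    functional_class: FunctionalClass
    patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(
                f"keyword set for {self.functional_class.value} is empty"
            )

    def matches(self, product: str) -> bool:
        low = product.lower()
        return any(p.lower() in low for p in self.patterns)


DEFAULT_KEYWORDS: tuple[KeywordSet, ...] = (
    KeywordSet(
        FunctionalClass.ETS_COMPLEX_I,
        (
            "NADH dehydrogenase",
            "NADH-quinone oxidoreductase",
            "NADH:ubiquinone oxidoreductase",
            "complex I",
            "nuo",
        ),
    ),
    KeywordSet(
        FunctionalClass.NA_TRANSPORT,
        (
            "sodium",
            "Na+/H+ antiporter",
            "Na+/Ca+2",
            "Na(+)",
            "bile acid symporter",
            "mrp antiporter",
        ),
    ),
    KeywordSet(
        FunctionalClass.ABC_TRANSPORT,
        (
            "ABC transporter",
            "ABC-type",
            "phosphate-binding",
            "phosphate ABC",
            "branched-chain amino acid transport",
            "periplasmic binding protein",
        ),
    ),
    KeywordSet(
        FunctionalClass.CHANNELS_PORES,
        (
            "porin",
            "channel",
            "mechanosensitive",
            "polymorphic membrane protein",
            "pore-forming",
        ),
    ),
)


def keyword_candidates(
    annotations: pd.DataFrame,
    keywords: Sequence[KeywordSet] = DEFAULT_KEYWORDS,
) -> dict[FunctionalClass, list[str]]:
    """Gene ids whose product string matches a class keyword.

    ``annotations`` needs ``id`` and ``product`` columns. A gene matching
    several classes is assigned to the first matching class in the given
    order; the collision is logged.
    """
    if not keywords:
        raise ValueError("at least one keyword set required")
    if not {"id", "product"} <= set(annotations.columns):
        raise ValueError("annotation table needs 'id' and 'product' columns")
    out: dict[FunctionalClass, list[str]] = {
        ks.functional_class: [] for ks in keywords
    }
    for row in annotations.itertuples(index=False):
        matched = [ks for ks in keywords if ks.matches(str(row.product))]
        if not matched:
            continue
        if len(matched) > 1:
            logger.info(
                "gene %s product %r matches classes %s; assigned %s",
                row.id,
                row.product,
                [m.functional_class.value for m in matched],
                matched[0].functional_class.value,
            )
        out[matched[0].functional_class].append(str(row.id))
    return out


def homology_candidates(
    queries: Sequence[ProteinRecord],
    genome: Sequence[ProteinRecord],
    cfg: Optional[ScreenConfig] = None,
) -> list[str]:
    """Genome genes whose best alignment to any seed query passes the
    homology-search thresholds (e-value analog and length fraction of the
    shorter over the longer sequence)."""
    cfg = cfg or ScreenConfig()
    if not queries:
        raise ValueError("no query proteins given")
    hits = []
    for gene in genome:
        for q in queries:
            res = align_pair(gene, q, cfg)
            len_frac = min(gene.length, q.length) / max(gene.length, q.length)
            if (
                res.evalue_analog < cfg.blast_evalue_max
                and len_frac >= cfg.min_hit_len_frac
            ):
                hits.append(gene.id)
                break
    return sorted(set(hits))


def load_keywords(path: str | Path) -> tuple[KeywordSet, ...]:
    """Read keyword sets from JSON: {"ets_complex_i": ["pattern", ...], ...}."""
    raw = json.loads(Path(path).read_text())
    return tuple(
        KeywordSet(FunctionalClass(cls), tuple(patterns))
        for cls, patterns in raw.items()
    )
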