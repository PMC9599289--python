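"""Offline gene annotation model and enrichment filters.

miRNA nomenclature distinguishes three processing tiers by prefix casing:
``MIR31`` is the gene, ``mir-31`` the precursor (pri/pre) transcript, and
``miR-31-5p`` a mature miRNA.  One precursor hairpin yields up to two mature
arms (5p and 3p); some families (e.g. miR-429) have a single annotated mature
form.

This module replaces live database lookups (exosome catalogues, disease
expression databases) with a flat per-gene annotation table carrying:

* ``exosomal`` — evidence that the mature products are found in exosomes;
* ``dir_pancreatitis_vs_healthy`` / ``dir_pdac_vs_pancreatitis`` — expression
  direction in the two disease contrasts, each one of ``up``, ``down``,
  ``none`` (evaluated, no signal) or ``unknown`` (never evaluated);
* ``mature_arms`` — the mature miR names the gene gives rise to.

``unknown`` and ``none`` are deliberately distinct: absence of evidence never
satisfies a filter, but it is reported differently.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass

from .errors import UnknownSymbolError, ValidationError

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "none", "unknown")
TIERS = ("gene", "precursor", "mature")

#: Directions that count as a known differential signal.
_DIFFERENTIAL = frozenset({"up", "down"})

_NAME_RE = re.compile(
    r"(?P<prefix>MIR|miR|mir)[-_ ]?(?P<core>\d+[A-Za-z]?\d*)(?:[-_ ](?P<arm>[35]p))?$"
)

_PREFIX_TIER = {"MIR": "gene", "mir": "precursor", "miR": "mature"}


def normalize_mir_name(name: str) -> tuple[str, str]:
    """Canonicalize a miRNA name and classify its processing tier.

    The tier is read off the prefix casing (``MIR``/``mir``/``miR``);
    separators are normalized to the conventional form.  Canonical names
    round-trip unchanged.

    Returns ``(canonical_name, tier)`` with tier in ``{"gene", "precursor",
    "mature"}``.  Raises :class:`ValidationError` on anything unparseable —
    never silently coerces.
    """
    if not isinstance(name, str) or not name.strip():
        raise ValidationError(f"empty or non-string miRNA name: {name!r}")
    text = name.strip()
    m = _NAME_RE.fullmatch(text)
    if m is None or m.group("prefix") not in _PREFIX_TIER:
        raise ValidationError(f"unparseable miRNA name: {name!r}")
    tier = _PREFIX_TIER[m.group("prefix")]
    core, arm = m.group("core"), m.group("arm")
    if tier == "gene":
        if arm is not None:
            raise ValidationError(
                f"{name!r}: a gene symbol (MIR prefix) cannot carry a mature arm suffix"
            )
        return "MIR" + core.upper(), tier
    if tier == "precursor":
        if arm is not None:
            raise ValidationError(
                f"{name!r}: a precursor name (mir prefix) cannot carry a mature arm suffix"
            )
        return "mir-" + core.lower(), tier
    canonical = "miR-" + core.lower()
    if arm is not None:
        canonical += "-" + arm.lower()
    return canonical, tier


def mature_family(mature_name: str) -> tuple[str, str | None]:
    """Split a mature miR name into (family, arm).

    ``miR-425-5p`` -> (``miR-425``, ``5p``); arm-less names such as
    ``miR-429`` map to (``miR-429``, None).  Works for non-human controls
    (``cel-miR-2-3p``) as well, which is why it is a plain suffix split.
    """
    for arm in ("5p", "3p"):
        if mature_name.endswith("-" + arm):
            return mature_name[: -(len(arm) + 1)], arm
    return mature_name, None


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene annotation record driving the enrichment filters."""

    symbol: str
    exosomal: bool
    dir_pancreatitis_vs_healthy: str = "unknown"
    dir_pdac_vs_pancreatitis: str = "unknown"
    mature_arms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for field in ("dir_pancreatitis_vs_healthy", "dir_pdac_vs_pancreatitis"):
            value = getattr(self, field)
            if value not in DIRECTIONS:
                raise ValidationError(
                    f"{self.symbol}: {field}={value!r} not in {DIRECTIONS}"
                )
        object.__setattr__(self, "mature_arms", tuple(self.mature_arms))

    @property
    def has_differential_signal(self) -> bool:
        return (
            self.dir_pancreatitis_vs_healthy in _DIFFERENTIAL
            or self.dir_pdac_vs_pancreatitis in _DIFFERENTIAL
        )


class AnnotationTable(Mapping[str, GeneAnnotation]):
    """Mapping from gene symbol to :class:`GeneAnnotation`, unique per symbol."""

    def __init__(self, annotations: Iterable[GeneAnnotation]):
        self._by_symbol: dict[str, GeneAnnotation] = {}
        for ann in annotations:
            if ann.symbol in self._by_symbol:
                raise ValidationError(f"duplicate annotation for symbol {ann.symbol!r}")
            self._by_symbol[ann.symbol] = ann

    def __getitem__(self, symbol: str) -> GeneAnnotation:
        try:
            return self._by_symbol[symbol]
        except KeyError:
            raise UnknownSymbolError(
                f"gene {symbol!r} has no annotation row"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._by_symbol)

    def __len__(self) -> int:
        return len(self._by_symbol)


def filter_exosomal(genes: Iterable[str], annotations: AnnotationTable) -> list[str]:
    """Keep genes with evidence of exosomal presence, input order preserved.

    Raises :class:`UnknownSymbolError` naming the first unannotated gene.
    """
    return [g for g in genes if annotations[g].exosomal]


def filter_disease_differential(
    genes: Iterable[str], annotations: AnnotationTable
) -> list[str]:
    """Keep genes with a known expression direction in either disease contrast.

    A gene passes when ``dir_pancreatitis_vs_healthy`` or
    ``dir_pdac_vs_pancreatitis`` is ``up`` or ``down``.  Genes whose evidence
    is entirely ``unknown`` are dropped with a warning (they were never
    evaluated, which is different from an evaluated ``none``).
    """
    kept: list[str] = []
    for g in genes:
        ann = annotations[g]
        if ann.has_differential_signal:
            kept.append(g)
        elif (
            ann.dir_pancreatitis_vs_healthy == "unknown"
            and ann.dir_pdac_vs_pancreatitis == "unknown"
        ):
            logger.warning(
                "%s dropped from differential filter: direction unknown in both "
                "contrasts (no evidence, as opposed to an evaluated 'none')",
                g,
            )
    return kept


def _arm_sort_key(arm_name: str) -> int:
    _, arm = mature_family(arm_name)
    return {"5p": 0, "3p": 1}.get(arm, 2) if arm else 0


def expand_to_mature(genes: Iterable[str], annotations: AnnotationTable) -> list[str]:
    """Expand gene symbols to their mature miR names, 5p before 3p per gene.

    Order follows the input gene order; duplicates across genes are removed
    keeping the first occurrence.  A gene annotated with no mature arm raises
    :class:`ValidationError`.
    """
    mature: list[str] = []
    seen: set[str] = set()
    for g in genes:
        arms = annotations[g].mature_arms
        if not arms:
            raise ValidationError(f"gene {g!r} has no annotated mature arm")
        for arm in sorted(arms, key=_arm_sort_key):
            if arm not in seen:
                seen.add(arm)
                mature.append(arm)
    return mature
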