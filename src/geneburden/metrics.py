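"""Normalisation of variant deleteriousness annotations onto a common scale.

In-silico pathogenicity predictors disagree wildly about units and
directionality: conservation scores such as GERP++ and phyloP are unbounded,
SIFT calls 0 "damaging" and 1 "tolerated", and MutationTaster's score means
different things depending on its own categorical prediction.  This module
maps any of sixteen supported metrics onto a single deleteriousness value
``D`` in ``[0, 1]`` with a uniform convention: 0 is benign, 1 is maximally
pathogenic.

The mapping is a linear rescale between per-metric bounds, followed by an
optional complement (``1 - x``) for metrics whose native direction is
inverted.  Bounds for the unbounded metrics are the extreme values observed
across the dbNSFP v3.3a SNV database; bounded metrics use their native
``(0, 1)`` range.  The default table ships in :mod:`geneburden.data` as a
plain YAML file and can be overridden by the user.

Two categorical rules sit alongside the numeric transform:

* protein-truncating variants (stopgain, stoploss, frameshifts) receive the
  maximal deleteriousness ``D = 1`` because most predictors do not score
  them at all;
* synonymous and splicing variants are excluded from gene scores entirely.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "MetricSpec",
    "RawAnnotation",
    "MetricConfigError",
    "AnnotationParseError",
    "METRIC_NAMES",
    "load_metric_table",
    "default_metric_table",
    "get_metric",
    "transform",
    "assign_truncating",
    "exclude_variant",
    "TRUNCATING_CLASSES",
    "EXCLUDED_CLASSES",
]

CATEGORIES = frozenset({"conservation", "functionality", "composite"})

#: Annotation classes assigned the maximal deleteriousness D = 1.
TRUNCATING_CLASSES = frozenset(
    {
        "stopgain",
        "stoploss",
        "frameshift insertion",
        "frameshift deletion",
        "frameshift substitution",
    }
)

#: Annotation classes excluded from gene scores altogether.
EXCLUDED_CLASSES = frozenset(
    {
        "synonymous snv",
        "synonymous",
        "splicing",
        "splice",
        "splice site",
    }
)

#: MutationTaster prediction classes for which the scaled score is kept
#: (disease_causing_automatic / disease_causing) versus complemented
#: (polymorphism / polymorphism_automatic).
_MT_KEEP = frozenset({"A", "D"})
_MT_FLIP = frozenset({"N", "P"})


class MetricConfigError(ValueError):
    """An unknown metric name or an invalid metric configuration."""


class AnnotationParseError(ValueError):
    """A raw annotation value that cannot be interpreted as a number."""


@dataclass(frozen=True)
class MetricSpec:
    """Identity, bounds, and transformation rule for one deleteriousness metric.

    Parameters
    ----------
    name
        Metric identifier, e.g. ``"CADD"``.
    category
        One of ``conservation``, ``functionality``, ``composite``.
    lower_bound, upper_bound
        Raw-score bounds used for clamping and linear rescaling.
    complement
        Take ``1 - x`` after rescaling (metrics where low raw = damaging).
    conditional_rule
        Optional rule name; ``"mutationtaster"`` switches the complement on
        the per-variant prediction class.
    """

    name: str
    category: str
    lower_bound: float
    upper_bound: float
    complement: bool = False
    conditional_rule: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise MetricConfigError(
                f"metric {self.name!r}: unknown category {self.category!r}"
            )
        if not self.lower_bound < self.upper_bound:
            raise MetricConfigError(
                f"metric {self.name!r}: lower bound {self.lower_bound} must be "
                f"strictly below upper bound {self.upper_bound}"
            )


@dataclass(frozen=True)
class RawAnnotation:
    """One metric's raw annotation for one variant allele.

    ``raw_value`` is ``None`` when the annotation database does not score the
    variant; that is distinct from a raw value of 0.  ``aux_class`` carries
    the MutationTaster prediction class (``A``, ``D``, ``N`` or ``P``) where
    applicable.
    """

    metric_name: str
    raw_value: float | None
    aux_class: str | None = None


def load_metric_table(path: str | None = None) -> dict[str, MetricSpec]:
    """Load a metric configuration table from YAML.

    With ``path=None`` the packaged default table is loaded.  The result maps
    metric name to :class:`MetricSpec`.
    """
    if path is None:
        text = resources.files("geneburden.data").joinpath("metrics.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise MetricConfigError("metric config must be a mapping of name -> stanza")
    table: dict[str, MetricSpec] = {}
    for name, stanza in raw.items():
        try:
            table[name] = MetricSpec(
                name=name,
                category=stanza["category"],
                lower_bound=float(stanza["lower"]),
                upper_bound=float(stanza["upper"]),
                complement=bool(stanza.get("complement", False)),
                conditional_rule=stanza.get("conditional"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise MetricConfigError(f"invalid stanza for metric {name!r}: {exc}") from exc
    return table


@functools.lru_cache(maxsize=1)
def default_metric_table() -> dict[str, MetricSpec]:
    """The packaged sixteen-metric table (cached)."""
    return load_metric_table(None)


METRIC_NAMES = tuple(sorted(load_metric_table(None)))


def get_metric(name: str, table: Mapping[str, MetricSpec] | None = None) -> MetricSpec:
    """Look up a metric by name, raising :class:`MetricConfigError` if unknown."""
    table = default_metric_table() if table is None else table
    try:
        return table[name]
    except KeyError:
        raise MetricConfigError(
            f"unknown metric {name!r}; supported: {', '.join(sorted(table))}"
        ) from None


def transform(raw: RawAnnotation | float | None, spec: MetricSpec) -> float | None:
    """Map one raw annotation onto the common deleteriousness scale ``D``.

    Raw values outside the configured bounds are clamped before rescaling, so
    the result is always in ``[0, 1]``.  Missing input gives missing output.
    For MutationTaster the prediction class decides the direction; a missing
    class makes the value unusable and yields missing.
    """
    if raw is None:
        return None
    if isinstance(raw, RawAnnotation):
        if raw.metric_name != spec.name:
            raise MetricConfigError(
                f"annotation for {raw.metric_name!r} passed to metric {spec.name!r}"
            )
        value, aux = raw.raw_value, raw.aux_class
    else:
        value, aux = raw, None
    if value is None:
        return None
    value = float(value)
    if value != value:  # NaN-style missing
        return None
    clamped = min(max(value, spec.lower_bound), spec.upper_bound)
    scaled = (clamped - spec.lower_bound) / (spec.upper_bound - spec.lower_bound)
    if spec.conditional_rule == "mutationtaster":
        if aux in _MT_KEEP:
            return scaled
        if aux in _MT_FLIP:
            return 1.0 - scaled
        return None
    if spec.complement:
        return 1.0 - scaled
    return scaled


def assign_truncating(functional_class: str) -> float | None:
    """Return the D = 1 override for protein-truncating classes, else ``None``.

    The override takes precedence over any raw metric annotation: predictors
    trained on nonsynonymous substitutions do not score stop or frameshift
    changes, whose impact on the protein is near-certain.
    """
    if functional_class is None:
        return None
    if functional_class.strip().lower() in TRUNCATING_CLASSES:
        return 1.0
    return None


def exclude_variant(functional_class: str) -> bool:
    """True for synonymous and splicing classes, which never enter a gene score."""
    if functional_class is None:
        return False
    return functional_class.strip().lower() in EXCLUDED_CLASSES
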