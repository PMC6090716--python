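"""INSDC feature-table definitions and location algebra.

The bundled tables enumerate the controlled vocabulary of the INSDC feature
table: 52 feature keys (CDS, mRNA, source, 3'UTR, ...) each with its
mandatory and optional qualifiers, and 98 qualifiers each with the format of
its expected value. Locations are segment lists in 1-based inclusive
coordinates with complement/partial flags, rendered to and parsed from the
INSDC location grammar ("complement(join(<1..200,300..>400))").
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

__all__ = [
    "DefinitionTables",
    "EmblFeature",
    "FeatureKeyDefinition",
    "Location",
    "LocationError",
    "QualifierDefinition",
    "build_location",
    "compute_codon_start",
    "check_qualifier_legality",
    "load_definitions",
    "parse_location",
    "render_location",
]


class LocationError(ValueError):
    """Invalid location (overlapping segments, bad grammar, ...)."""


@dataclass(frozen=True)
class FeatureKeyDefinition:
    key: str
    mandatory_qualifiers: tuple[str, ...]
    optional_qualifiers: tuple[str, ...]

    @property
    def legal_qualifiers(self) -> frozenset[str]:
        return frozenset(self.mandatory_qualifiers) | frozenset(self.optional_qualifiers)


@dataclass(frozen=True)
class QualifierDefinition:
    name: str
    value_format: str  # none | quoted-text | unquoted-token | integer
    definition: str = ""
    comment: str = ""


@dataclass(frozen=True)
class DefinitionTables:
    """The feature-key and qualifier tables, keyed by exact name."""

    feature_keys: dict[str, FeatureKeyDefinition]
    qualifiers: dict[str, QualifierDefinition]

    def qualifier_by_casefold(self, name: str) -> QualifierDefinition | None:
        """Case-insensitive qualifier probe, returning the canonical entry."""
        return {q.casefold(): d for q, d in self.qualifiers.items()}.get(name.casefold())

    def feature_key_by_casefold(self, key: str) -> FeatureKeyDefinition | None:
        return {k.casefold(): d for k, d in self.feature_keys.items()}.get(key.casefold())


@lru_cache(maxsize=1)
def load_definitions() -> DefinitionTables:
    """Load the bundled INSDC definition tables (cached)."""
    pkg = resources.files("gff2embl.data")
    raw_features = json.loads((pkg / "embl_feature_keys.json").read_text())
    raw_qualifiers = json.loads((pkg / "embl_qualifiers.json").read_text())
    feature_keys = {
        key: FeatureKeyDefinition(key, tuple(d["mandatory"]), tuple(d["optional"]))
        for key, d in raw_features.items()
    }
    qualifiers = {
        name: QualifierDefinition(name, d["format"], d.get("definition", ""),
                                  d.get("comment", ""))
        for name, d in raw_qualifiers.items()
    }
    return DefinitionTables(feature_keys=feature_keys, qualifiers=qualifiers)


@dataclass
class Location:
    """An INSDC feature location: sorted non-overlapping 1-based segments.

    ``partial5``/``partial3`` are expressed in feature orientation (5' end of
    the feature itself); rendering converts them to genomic bounds so that
    "<" always marks the lower and ">" the upper genomic coordinate.
    """

    segments: list[tuple[int, int]]
    complement: bool = False
    partial5: bool = False
    partial3: bool = False

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]


@dataclass
class EmblFeature:
    """One feature-table entry: key, location, ordered qualifiers.

    Qualifier values of ``None`` mark valueless qualifiers such as /pseudo.
    """

    key: str
    location: Location
    qualifiers: list[tuple[str, str | None]] = field(default_factory=list)

    def add_qualifier(self, name: str, value: str | None = None) -> None:
        self.qualifiers.append((name, value))


def build_location(segments: list[tuple[int, int]], strand: str = "+",
                   partial5: bool = False, partial3: bool = False) -> Location:
    """Validate and normalise segments into a Location.

    ``strand`` "-" sets the complement flag; "." and "?" render unstranded
    (forward). Overlapping segments are an error naming the offending pair.
    """
    if not segments:
        raise LocationError("a location needs at least one segment")
    for start, end in segments:
        if start < 1:
            raise LocationError(f"coordinate {start} < 1")
        if start > end:
            raise LocationError(f"segment start {start} > end {end}")
    ordered = sorted(segments)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 <= e1:
            raise LocationError(f"overlapping segments ({s1},{e1}) and ({s2},{e2})")
    return Location(segments=ordered, complement=(strand == "-"),
                    partial5=partial5, partial3=partial3)


def render_location(loc: Location) -> str:
    """Render a Location to the INSDC grammar.

    Single segments render "start..end" (single bases as "n..n"); several
    segments join. complement() wraps the whole expression. Partial markers
    attach in genomic coordinates: "<" on the lower genomic bound, ">" on the
    upper, whichever feature end they came from.
    """
    low_open = loc.partial3 if loc.complement else loc.partial5
    high_open = loc.partial5 if loc.complement else loc.partial3
    parts = []
    for i, (start, end) in enumerate(loc.segments):
        left = f"<{start}" if (low_open and i == 0) else str(start)
        right = f">{end}" if (high_open and i == len(loc.segments) - 1) else str(end)
        parts.append(f"{left}..{right}")
    text = parts[0] if len(parts) == 1 else "join(" + ",".join(parts) + ")"
    return f"complement({text})" if loc.complement else text


_SEGMENT_RE = re.compile(r"^(<?)(\d+)(?:\.\.(>?)(\d+))?$")


def parse_location(text: str) -> Location:
    """Parse the subset of the INSDC location grammar this package emits.

    Handles segment, join(...) and a complement(...) wrapper; "<"/">" partial
    markers on the outermost genomic bounds. Raises LocationError otherwise.
    """
    text = text.strip()
    complement = False
    if text.startswith("complement(") and text.endswith(")"):
        complement = True
        text = text[len("complement("):-1]
    if text.startswith("join(") and text.endswith(")"):
        inner = text[len("join("):-1]
        parts = inner.split(",")
        if len(parts) < 2:
            raise LocationError(f"join() needs at least two segments: {text!r}")
    else:
        parts = [text]
    segments: list[tuple[int, int]] = []
    low_open = high_open = False
    for i, part in enumerate(parts):
        m = _SEGMENT_RE.match(part.strip())
        if not m:
            raise LocationError(f"unparseable location segment {part!r}")
        lt, start_s, gt, end_s = m.groups()
        start = int(start_s)
        end = int(end_s) if end_s is not None else start
        if lt:
            if i != 0:
                raise LocationError(f"'<' only legal on the first segment: {part!r}")
            low_open = True
        if gt:
            if i != len(parts) - 1:
                raise LocationError(f"'>' only legal on the last segment: {part!r}")
            high_open = True
        segments.append((start, end))
    loc = build_location(segments, "-" if complement else "+")
    if complement:
        loc.partial5, loc.partial3 = high_open, low_open
    else:
        loc.partial5, loc.partial3 = low_open, high_open
    return loc


def compute_codon_start(cds_segments: list[tuple[int, int]], strand: str,
                        phases: list[int | None]) -> tuple[int, list[str]]:
    """codon_start (1, 2 or 3) from the GFF3 phase of the first translated segment.

    The first translated segment is the genomic-leftmost on "+" (and for
    unstranded features) and the genomic-rightmost on "-". An absent phase is
    treated as 0 with a warning. Returns (codon_start, warnings).
    """
    if len(cds_segments) != len(phases):
        raise ValueError("phases must align with segments")
    warnings: list[str] = []
    if strand == "-":
        idx = max(range(len(cds_segments)), key=lambda i: cds_segments[i][0])
    else:
        idx = min(range(len(cds_segments)), key=lambda i: cds_segments[i][0])
    phase = phases[idx]
    if phase is None:
        warnings.append("first translated CDS segment has no phase; assuming 0")
        phase = 0
    if phase not in (0, 1, 2):
        raise ValueError(f"phase {phase} outside 0..2")
    return phase + 1, warnings


def check_qualifier_legality(feature: EmblFeature,
                             defs: DefinitionTables | None = None) -> list[str]:
    """Report qualifier-placement problems for one feature (warning level).

    Flags qualifiers outside the key's mandatory+optional set and mandatory
    qualifiers that are absent. Unknown keys/qualifiers are also reported.
    """
    defs = defs or load_definitions()
    violations: list[str] = []
    key_def = defs.feature_keys.get(feature.key)
    if key_def is None:
        violations.append(f"unknown feature key {feature.key!r}")
        return violations
    present = {name for name, _ in feature.qualifiers}
    for name in present:
        if name not in defs.qualifiers:
            violations.append(f"unknown qualifier {name!r} on {feature.key}")
        elif name not in key_def.legal_qualifiers:
            violations.append(f"qualifier {name!r} not legal on feature key {feature.key}")
    for name in key_def.mandatory_qualifiers:
        if name not in present:
            violations.append(f"mandatory qualifier {name!r} missing on {feature.key}")
    return violations
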