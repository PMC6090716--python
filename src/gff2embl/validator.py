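"""Structural validation of EMBL flat-file text.

A desk-scale, dependency-free stand-in for the archive's own flat-file
validator: it checks the structural rules a submission must satisfy, not the
biological content. Rule catalogue (rule_id -> check):

* ``LINE_LENGTH``        — every line is at most 80 characters
* ``LINE_CODE``          — every line starts with a known two-letter code
* ``LINE_ORDER``         — codes appear in legal order (ID .. FT .. SQ .. //)
* ``MISSING_TERMINATOR`` — every entry ends with "//"
* ``ID_FORMAT``          — the ID line parses and declares the length in BP
* ``FT_COLUMNS``         — feature keys sit in columns 6-20, text at 22
* ``UNKNOWN_KEY``        — every feature key is in the 52-key table
* ``UNKNOWN_QUALIFIER``  — every qualifier is in the 98-name table
* ``LOCATION_SYNTAX``    — every location parses under the INSDC grammar
* ``COORD_RANGE``        — coordinates stay within the declared length
* ``SOURCE_FIRST``       — a source feature exists, first, spanning 1..length
* ``QUALIFIER_PLACEMENT``— qualifier legal on its key (warning)
* ``MANDATORY_MISSING``  — mandatory qualifiers present (warning)
* ``SQ_COUNTS``          — SQ composition counts match the sequence lines
* ``SQ_FORMAT``          — sequence lines carry correct cumulative counts

Only ``error`` severity makes a file unacceptable; ``warning`` findings are
advisory, mirroring how the conversion itself reports but does not block.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .feature_table import (DefinitionTables, EmblFeature, LocationError,
                            check_qualifier_legality, load_definitions,
                            parse_location)

__all__ = ["Violation", "validate_flat_file"]

_LEGAL_CODES = {"ID", "AC", "PR", "DT", "DE", "KW", "OS", "OC", "OG", "RN",
                "RC", "RP", "RX", "RG", "RA", "RT", "RL", "DR", "CC", "AS",
                "FH", "FT", "SQ", "CO", "XX"}
# rank order of line codes within one entry; XX separators are rank-free
_ORDER = {"ID": 0, "AC": 1, "PR": 2, "DT": 3, "DE": 4, "KW": 5, "OS": 6,
          "OC": 6, "OG": 6, "RN": 7, "RC": 7, "RP": 7, "RX": 7, "RG": 7,
          "RA": 7, "RT": 7, "RL": 7, "DR": 8, "CC": 9, "AS": 9, "FH": 10,
          "FT": 11, "CO": 12, "SQ": 13}

_ID_RE = re.compile(r"^ID   [^;]+; [^;]+; (linear|circular); [^;]+; [^;]+; "
                    r"[A-Z]{3}; (\d+) BP\.$")
_SQ_RE = re.compile(r"^SQ   Sequence (\d+) BP; (\d+) A; (\d+) C; (\d+) G; "
                    r"(\d+) T; (\d+) other;$")


@dataclass(frozen=True)
class Violation:
    line_number: int
    rule_id: str
    message: str
    severity: str = "error"


@dataclass
class _RawFeature:
    key: str
    line_number: int
    location_text: str
    qualifier_lines: list[tuple[int, str]]


def _split_entries(lines: list[str]) -> list[list[tuple[int, str]]]:
    entries: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        current.append((lineno, line))
        if line.rstrip() == "//":
            entries.append(current)
            current = []
    if current and any(line.strip() for _, line in current):
        entries.append(current)
    return entries


def _parse_qualifiers(raw: _RawFeature,
                      violations: list[Violation]) -> list[tuple[str, str | None]]:
    qualifiers: list[tuple[str, str | None]] = []
    buffer: list[tuple[int, str]] = []
    # group wrapped qualifier lines: a new qualifier starts with "/" when no
    # quoted value is left open (doubled "" escapes keep the parity intact)
    groups: list[list[tuple[int, str]]] = []
    open_quotes = False
    for lineno, text in raw.qualifier_lines:
        if text.startswith("/") and not open_quotes:
            if buffer:
                groups.append(buffer)
            buffer = [(lineno, text)]
        else:
            buffer.append((lineno, text))
        open_quotes = "".join(t for _, t in buffer).count('"') % 2 == 1
    if buffer:
        groups.append(buffer)
    for group in groups:
        lineno, first = group[0]
        m = re.match(r"^/([A-Za-z_][A-Za-z_0-9]*)(?:=(.*))?$", first, re.S)
        if not m:
            violations.append(Violation(lineno, "FT_COLUMNS",
                                        f"unparseable qualifier line {first!r}"))
            continue
        qualifiers.append((m.group(1), m.group(2)))
    return qualifiers


def _check_feature(raw: _RawFeature, declared_length: int | None,
                   defs: DefinitionTables, violations: list[Violation]) -> None:
    if raw.key not in defs.feature_keys:
        violations.append(Violation(raw.line_number, "UNKNOWN_KEY",
                                    f"unknown feature key {raw.key!r}"))
    try:
        location = parse_location(raw.location_text)
    except LocationError as exc:
        violations.append(Violation(raw.line_number, "LOCATION_SYNTAX",
                                    f"bad location {raw.location_text!r}: {exc}"))
        location = None
    if location is not None and declared_length is not None \
            and location.end > declared_length:
        violations.append(Violation(
            raw.line_number, "COORD_RANGE",
            f"feature {raw.key} extends to {location.end}, beyond the "
            f"declared length {declared_length}"))
    qualifiers = _parse_qualifiers(raw, violations)
    for name, _ in qualifiers:
        if name not in defs.qualifiers:
            violations.append(Violation(raw.line_number, "UNKNOWN_QUALIFIER",
                                        f"unknown qualifier {name!r} on {raw.key}"))
    if raw.key in defs.feature_keys and location is not None:
        feature = EmblFeature(key=raw.key, location=location,
                              qualifiers=[(n, v) for n, v in qualifiers])
        for message in check_qualifier_legality(feature, defs):
            if message.startswith("unknown qualifier"):
                continue  # already reported as UNKNOWN_QUALIFIER
            rule = "MANDATORY_MISSING" if "missing" in message else "QUALIFIER_PLACEMENT"
            violations.append(Violation(raw.line_number, rule, message,
                                        severity="warning"))


def _validate_entry(entry: list[tuple[int, str]], defs: DefinitionTables,
                    violations: list[Violation]) -> None:
    first_lineno = entry[0][0]
    if entry[-1][1].rstrip() != "//":
        violations.append(Violation(entry[-1][0], "MISSING_TERMINATOR",
                                    "entry does not end with '//'"))
    declared_length: int | None = None
    last_rank = -1
    features: list[_RawFeature] = []
    current: _RawFeature | None = None
    in_sq = False
    sq_header: tuple[int, ...] | None = None
    sq_lineno = 0
    residues: list[str] = []
    cumulative_ok = True

    for lineno, line in entry:
        if line.rstrip() == "//":
            break
        if in_sq:
            if not line.startswith("     "):
                violations.append(Violation(lineno, "LINE_CODE",
                                            "non-sequence line inside SQ block"))
                continue
            tokens = line.split()
            if not tokens or not tokens[-1].isdigit():
                violations.append(Violation(lineno, "SQ_FORMAT",
                                            "sequence line lacks a trailing count"))
                continue
            chunk = "".join(tokens[:-1])
            residues.append(chunk)
            if int(tokens[-1]) != sum(len(c) for c in residues):
                cumulative_ok = False
                violations.append(Violation(lineno, "SQ_FORMAT",
                                            "cumulative residue count mismatch"))
            continue
        code = line[:2]
        if code not in _LEGAL_CODES:
            violations.append(Violation(lineno, "LINE_CODE",
                                        f"unknown line code {line[:2]!r}"))
            continue
        if code == "XX":
            continue
        rank = _ORDER[code]
        if rank < last_rank:
            violations.append(Violation(lineno, "LINE_ORDER",
                                        f"line code {code} out of order"))
        last_rank = max(last_rank, rank)
        if code == "ID":
            if lineno != first_lineno:
                violations.append(Violation(lineno, "LINE_ORDER",
                                            "ID is not the first line of the entry"))
            m = _ID_RE.match(line.rstrip())
            if not m:
                violations.append(Violation(lineno, "ID_FORMAT",
                                            f"unparseable ID line {line!r}"))
            else:
                declared_length = int(m.group(2))
        elif code == "FT":
            key_field = line[5:21]
            body = line[21:]
            if key_field.strip():
                if line[5] == " " or not body.strip():
                    violations.append(Violation(
                        lineno, "FT_COLUMNS",
                        "feature key must start at column 6 with its "
                        "location at column 22"))
                    continue
                if current is not None:
                    features.append(current)
                current = _RawFeature(key=key_field.strip(), line_number=lineno,
                                      location_text=body.strip(),
                                      qualifier_lines=[])
            else:
                if current is None:
                    violations.append(Violation(lineno, "FT_COLUMNS",
                                                "FT continuation before any feature"))
                    continue
                text = body.strip()
                if not current.qualifier_lines and not text.startswith("/"):
                    current.location_text += text  # wrapped location
                else:
                    current.qualifier_lines.append((lineno, text))
        elif code == "SQ":
            m = _SQ_RE.match(line.rstrip())
            if not m:
                violations.append(Violation(lineno, "SQ_COUNTS",
                                            f"unparseable SQ header {line!r}"))
            else:
                sq_header = tuple(int(g) for g in m.groups())
                sq_lineno = lineno
            in_sq = True
    if current is not None:
        features.append(current)

    if not features:
        violations.append(Violation(first_lineno, "SOURCE_FIRST",
                                    "entry has no feature table"))
    else:
        first = features[0]
        if first.key != "source":
            violations.append(Violation(first.line_number, "SOURCE_FIRST",
                                        "first feature is not source"))
        elif declared_length is not None:
            try:
                loc = parse_location(first.location_text)
                if (loc.start, loc.end) != (1, declared_length):
                    violations.append(Violation(
                        first.line_number, "SOURCE_FIRST",
                        f"source spans {loc.start}..{loc.end}, not "
                        f"1..{declared_length}"))
            except LocationError:
                pass  # reported by _check_feature
        if sum(1 for f in features if f.key == "source") > 1:
            violations.append(Violation(first.line_number, "SOURCE_FIRST",
                                        "multiple source features",
                                        severity="warning"))
    for raw in features:
        _check_feature(raw, declared_length, defs, violations)

    sequence = "".join(residues)
    if sq_header is not None:
        length, a, c, g, t, other = sq_header
        lowered = sequence.lower()
        actual = (len(lowered), lowered.count("a"), lowered.count("c"),
                  lowered.count("g"), lowered.count("t"),
                  len(lowered) - sum(lowered.count(b) for b in "acgt"))
        if cumulative_ok and actual != (length, a, c, g, t, other):
            violations.append(Violation(
                sq_lineno, "SQ_COUNTS",
                f"SQ header declares {sq_header} but the sequence lines "
                f"give {actual}"))
        if declared_length is not None and length != declared_length:
            violations.append(Violation(sq_lineno, "SQ_COUNTS",
                                        "SQ length differs from the ID line"))


def validate_flat_file(text: str,
                       defs: DefinitionTables | None = None) -> list[Violation]:
    """Run every structural check; returns all violations (never raises)."""
    defs = defs or load_definitions()
    violations: list[Violation] = []
    lines = text.splitlines()
    for lineno, line in enumerate(lines, start=1):
        if len(line) > 80:
            violations.append(Violation(lineno, "LINE_LENGTH",
                                        f"line is {len(line)} characters long"))
    for entry in _split_entries(lines):
        _validate_entry(entry, defs, violations)
    return violations
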