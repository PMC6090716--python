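"""Controlled-vocabulary mapping between GFF3 terms and the INSDC feature table.

Three JSON tables drive the conversion and can be replaced by user-edited
copies:

* ``translation_gff_feature_to_embl_feature.json`` — GFF3 feature type
  (column 3) to EMBL feature key, or ``{"remove": true}`` to drop it;
* ``translation_gff_attribute_to_embl_qualifier.json`` — GFF3 attribute tag
  (column 9) to EMBL qualifier, with optional per-value prefix/suffix;
* ``translation_gff_other_to_embl_qualifier.json`` — the ``source`` (column
  2) and ``score`` (column 6) pseudo-tags to qualifiers.

When no rule exists, a term identical to an EMBL feature key or qualifier
name passes through unchanged (identity fallback, probed case-insensitively);
anything else is skipped and the caller reports it once per distinct term.
"""

from __future__ import annotations

import difflib
import json
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .feature_table import DefinitionTables, load_definitions

__all__ = [
    "FeatureMappingRule",
    "MappingError",
    "MappingRuleSet",
    "QualifierMappingRule",
    "TRANSLATION_FILES",
    "expose_translations",
    "load_default_rules",
    "load_rules",
    "translate_attribute",
    "translate_feature_type",
    "Mapped",
    "Removed",
    "Skipped",
    "Unknown",
]

TRANSLATION_FILES = (
    "translation_gff_feature_to_embl_feature.json",
    "translation_gff_attribute_to_embl_qualifier.json",
    "translation_gff_other_to_embl_qualifier.json",
)


class MappingError(ValueError):
    """Malformed or illegal mapping table."""


@dataclass(frozen=True)
class FeatureMappingRule:
    source_type: str
    target: str | None = None
    remove: bool = False


@dataclass(frozen=True)
class QualifierMappingRule:
    source_tag: str
    targets: tuple[str, ...] = ()
    prefix: str = ""
    suffix: str = ""
    remove: bool = False


@dataclass(frozen=True)
class MappingRuleSet:
    """The three resolved translation tables; lookup is exact and case-sensitive."""

    feature_rules: dict[str, FeatureMappingRule] = field(default_factory=dict)
    qualifier_rules: dict[str, QualifierMappingRule] = field(default_factory=dict)
    column_rules: dict[str, QualifierMappingRule] = field(default_factory=dict)


# --- translation outcomes -------------------------------------------------

@dataclass(frozen=True)
class Mapped:
    key: str


class Removed:
    """Term explicitly dropped by a remove rule."""


class Unknown:
    """Feature type with no rule and no identity match; caller skips + warns."""


class Skipped:
    """Attribute tag with no rule and no identity match; caller warns."""


def _suggest(name: str, candidates) -> str:
    close = difflib.get_close_matches(name, list(candidates), n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def _parse_feature_rules(text: str, filename: str,
                         defs: DefinitionTables) -> dict[str, FeatureMappingRule]:
    try:
        raw = json.loads(text) if text.strip() else {}
    except json.JSONDecodeError as exc:
        raise MappingError(f"{filename}: malformed JSON ({exc})") from exc
    rules: dict[str, FeatureMappingRule] = {}
    warnings: list[str] = []
    for source, body in raw.items():
        if not isinstance(body, dict):
            raise MappingError(f"{filename}: entry {source!r} is not an object")
        for key in body:
            if key not in ("target", "remove"):
                warnings.append(f"{filename}: entry {source!r} has unknown key {key!r}; ignored")
        if body.get("remove"):
            rules[source] = FeatureMappingRule(source, remove=True)
            continue
        target = body.get("target")
        if target is None:
            rules[source] = FeatureMappingRule(source, remove=True)
            continue
        if target not in defs.feature_keys:
            raise MappingError(
                f"{filename}: entry {source!r} maps to {target!r}, which is not "
                f"an EMBL feature key{_suggest(target, defs.feature_keys)}")
        rules[source] = FeatureMappingRule(source, target=target)
    return rules


def _parse_qualifier_rules(text: str, filename: str,
                           defs: DefinitionTables) -> dict[str, QualifierMappingRule]:
    try:
        raw = json.loads(text) if text.strip() else {}
    except json.JSONDecodeError as exc:
        raise MappingError(f"{filename}: malformed JSON ({exc})") from exc
    rules: dict[str, QualifierMappingRule] = {}
    for source, body in raw.items():
        if not isinstance(body, dict):
            raise MappingError(f"{filename}: entry {source!r} is not an object")
        if body.get("remove"):
            rules[source] = QualifierMappingRule(source, remove=True)
            continue
        target = body.get("target")
        if target is None:
            rules[source] = QualifierMappingRule(source, remove=True)
            continue
        targets = tuple(target) if isinstance(target, list) else (target,)
        for t in targets:
            if t not in defs.qualifiers:
                raise MappingError(
                    f"{filename}: entry {source!r} maps to {t!r}, which is not "
                    f"an EMBL qualifier{_suggest(t, defs.qualifiers)}")
        rules[source] = QualifierMappingRule(
            source, targets=targets,
            prefix=str(body.get("prefix", "")), suffix=str(body.get("suffix", "")))
    return rules


def load_rules(feature_json: str, attribute_json: str, other_json: str,
               defs: DefinitionTables | None = None) -> MappingRuleSet:
    """Build a MappingRuleSet from the three JSON texts.

    Every target is checked against the definition tables at load time;
    illegal targets raise :class:`MappingError` naming the entry and the
    nearest legal name. Empty texts yield a fallback-only rule set.
    """
    defs = defs or load_definitions()
    return MappingRuleSet(
        feature_rules=_parse_feature_rules(feature_json, TRANSLATION_FILES[0], defs),
        qualifier_rules=_parse_qualifier_rules(attribute_json, TRANSLATION_FILES[1], defs),
        column_rules=_parse_qualifier_rules(other_json, TRANSLATION_FILES[2], defs),
    )


def load_default_rules(defs: DefinitionTables | None = None,
                       feature_path: str | Path | None = None,
                       attribute_path: str | Path | None = None,
                       other_path: str | Path | None = None) -> MappingRuleSet:
    """Load the bundled tables, any of them overridable by a user file path."""
    pkg = resources.files("gff2embl.data")
    texts = []
    for name, override in zip(TRANSLATION_FILES,
                              (feature_path, attribute_path, other_path)):
        if override is not None:
            texts.append(Path(override).read_text())
        else:
            texts.append((pkg / name).read_text())
    return load_rules(*texts, defs=defs)


def translate_feature_type(ftype: str, rules: MappingRuleSet,
                           defs: DefinitionTables | None = None):
    """Resolve a GFF3 feature type to Mapped(key), Removed or Unknown.

    Total function: never raises, whatever the input string.
    """
    defs = defs or load_definitions()
    rule = rules.feature_rules.get(ftype)
    if rule is not None:
        return Removed if rule.remove else Mapped(rule.target)
    hit = defs.feature_key_by_casefold(ftype)
    if hit is not None:
        return Mapped(hit.key)
    return Unknown


def translate_attribute(tag: str, values: list[str], rules: MappingRuleSet,
                        defs: DefinitionTables | None = None,
                        column: bool = False):
    """Resolve one attribute tag to [(qualifier, rendered value), ...].

    Rule hits produce one pair per value per target qualifier, each value
    wrapped as prefix+value+suffix. Without a rule, a tag matching a
    qualifier name (case-insensitive probe, canonical casing out) passes
    through; otherwise returns Skipped (or Removed for an explicit remove
    rule). ``column=True`` consults the source/score column table.
    """
    defs = defs or load_definitions()
    table = rules.column_rules if column else rules.qualifier_rules
    rule = table.get(tag)
    if rule is not None:
        if rule.remove:
            return Removed
        return [(target, f"{rule.prefix}{value}{rule.suffix}")
                for value in values for target in rule.targets]
    if not column:
        hit = defs.qualifier_by_casefold(tag)
        if hit is not None:
            return [(hit.name, value) for value in values]
    return Skipped


def expose_translations(destination: str | Path, force: bool = False) -> list[Path]:
    """Copy the bundled translation tables into ``destination`` for editing.

    Refuses to overwrite existing copies unless ``force``. Returns the paths
    written.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    targets = [dest / name for name in TRANSLATION_FILES]
    if not force:
        existing = [p.name for p in targets if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {', '.join(existing)} in {dest} (use force)")
    pkg = resources.files("gff2embl.data")
    written = []
    for name, target in zip(TRANSLATION_FILES, targets):
        with resources.as_file(pkg / name) as src:
            shutil.copyfile(src, target)
        written.append(target)
    return written
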