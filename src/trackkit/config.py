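"""Two-dialect configuration system, precedence merging, track lists, and
faceted track metadata.

Configuration can be split across several locations — query-URL parameters,
an in-code configuration object, top-level configuration files, per-dataset
files, and files any of those recursively include — merged so that
higher-precedence sources win key-by-key, with subtrees merging recursively.
Each resolved value remembers which source supplied it (provenance).

Two file dialects are supported: JSON (an object root) and a GBrowse-style
textual format::

    # comment
    [tracks.genes]          ; dotted headers nest
    key = Genes
    about = a value continued
      on an indented line
    feature_color = function(feature) { ... }   ; kept verbatim, never run

Textual values are typed: integer/float literals, ``true``/``false`` and
JSON-style lists are coerced; anything else is a string. Values beginning
with ``function(`` are opaque callback strings that pass through untouched.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "ConfigTree",
    "TrackStanza",
    "TrackMetadata",
    "parse_conf",
    "emit_conf",
    "parse_json_config",
    "emit_json_config",
    "parse_query_params",
    "merge_configs",
    "load_config_file",
    "add_track",
    "remove_track",
    "emit_track_list",
    "parse_track_list",
    "load_metadata",
    "facet_filter",
]


@dataclass
class ConfigTree:
    """Nested string-keyed mapping plus per-leaf provenance.

    ``data`` holds scalars, lists, or nested dicts; ``provenance`` maps a
    dotted key path to the name of the source that supplied its value.
    ``includes`` lists include directives found while parsing (resolved by
    :func:`load_config_file`, not by the parser itself).
    """

    data: dict = field(default_factory=dict)
    source: str = "?"
    provenance: dict[str, str] = field(default_factory=dict)
    includes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = {
                path: self.source for path in _leaf_paths(self.data)
            }

    def get(self, dotted: str, default=None):
        node = self.data
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                return default
            node = node[part]
        return node

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConfigTree):
            return NotImplemented
        return self.data == other.data


def _leaf_paths(node, prefix=""):
    if isinstance(node, dict):
        for key, value in node.items():
            yield from _leaf_paths(value, f"{prefix}{key}." if prefix or key else key)
    else:
        yield prefix.rstrip(".")


def _leaves(node, prefix=""):
    if isinstance(node, dict) and node:
        for key, value in node.items():
            yield from _leaves(value, f"{prefix}.{key}" if prefix else key)
    else:
        yield prefix, node


# ---------------------------------------------------------------------------
# Textual dialect


_SECTION_RE = re.compile(r"^\[([^\[\]]+)\]\s*$")
_INT_RE = re.compile(r"^[+-]?\d+$")
_FLOAT_RE = re.compile(r"^[+-]?(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?$")


def _strip_comment(line: str) -> str:
    out = []
    in_quotes = False
    for c in line:
        if c == '"':
            in_quotes = not in_quotes
        if c == "#" and not in_quotes:
            break
        out.append(c)
    return "".join(out)


def _coerce(raw: str):
    if raw.startswith("function("):
        return raw
    if _INT_RE.match(raw):
        return int(raw)
    if _FLOAT_RE.match(raw) and not _INT_RE.match(raw):
        return float(raw)
    if raw == "true":
        return True
    if raw == "false":
        return False
    if raw.startswith("["):
        try:
            return json.loads(raw)
        except json.JSONDecodeError:
            return raw
    return raw


def parse_conf(text: str, source: str = "conf") -> ConfigTree:
    """Parse the textual stanza dialect into a ConfigTree.

    ``include <path>`` directives are recorded on the tree for the loader to
    resolve; callback values (``function(...)``) are preserved verbatim.
    """
    tree = ConfigTree(source=source)
    section: list[str] = []
    current_key: list[str] | None = None
    current_value: list[str] = []
    includes: list[str] = []

    def settle() -> None:
        nonlocal current_key, current_value
        if current_key is not None:
            raw = "\n".join(current_value).strip()
            _assign(tree.data, current_key, _coerce(raw))
            tree.provenance[".".join(current_key)] = source
        current_key, current_value = None, []

    for lineno, rawline in enumerate(text.splitlines(), 1):
        line = _strip_comment(rawline)
        if current_key is not None and line[:1] in (" ", "\t") and line.strip():
            current_value.append(line.strip())
            continue
        stripped = line.strip()
        if not stripped:
            continue
        m = _SECTION_RE.match(stripped)
        if m is not None:
            settle()
            section = m.group(1).strip().split(".")
            if not all(section):
                raise ValueError(f"conf line {lineno}: empty section component")
            continue
        if stripped.startswith("include "):
            settle()
            includes.append(stripped[len("include "):].strip())
            continue
        if "=" not in stripped:
            raise ValueError(
                f"conf line {lineno}: expected 'key = value' or '[section]', got {rawline!r}"
            )
        settle()
        key, _, value = stripped.partition("=")
        key = key.strip()
        if not key:
            raise ValueError(f"conf line {lineno}: empty key")
        current_key = section + key.split(".")
        current_value = [value.strip()]
    settle()
    tree.includes = includes
    return tree


def _assign(node: dict, path: list[str], value) -> None:
    for part in path[:-1]:
        nxt = node.get(part)
        if not isinstance(nxt, dict):
            nxt = {}
            node[part] = nxt
        node = nxt
    node[path[-1]] = value


def _format_conf_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, list):
        return json.dumps(value)
    return str(value)


def emit_conf(tree: ConfigTree) -> str:
    """Deterministic textual emission (sorted sections and keys).

    Top-level scalar keys come first, then one ``[section]`` per first-level
    subtree with its leaves as dotted keys. Multi-line values are emitted as
    indented continuations.
    """
    lines: list[str] = []

    def emit_pair(key: str, value) -> None:
        text = _format_conf_value(value)
        parts = text.split("\n")
        lines.append(f"{key} = {parts[0]}")
        for cont in parts[1:]:
            lines.append(f"  {cont}")

    top = tree.data
    for key in sorted(k for k, v in top.items() if not isinstance(v, dict)):
        emit_pair(key, top[key])
    for section in sorted(k for k, v in top.items() if isinstance(v, dict)):
        lines.append("")
        lines.append(f"[{section}]")
        for dotted, value in sorted(_leaves(top[section])):
            emit_pair(dotted, value)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON dialect


def parse_json_config(text: str, source: str = "json") -> ConfigTree:
    data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError("JSON configuration root must be an object")
    return ConfigTree(data=data, source=source)


def emit_json_config(tree: ConfigTree) -> str:
    """Byte-stable JSON emission (sorted keys, fixed indentation)."""
    return json.dumps(tree.data, sort_keys=True, indent=2) + "\n"


def parse_query_params(params: dict[str, str] | str, source: str = "url") -> ConfigTree:
    """Flat ``a.b.c=value`` query parameters as a nested tree."""
    if isinstance(params, str):
        pairs = [p.partition("=")[::2] for p in params.lstrip("?").split("&") if p]
        params = {k: v for k, v in pairs}
    tree = ConfigTree(source=source)
    for dotted, raw in params.items():
        _assign(tree.data, dotted.split("."), _coerce(raw) if isinstance(raw, str) else raw)
        tree.provenance[dotted] = source
    return tree


# ---------------------------------------------------------------------------
# Merging


def merge_configs(sources: list[ConfigTree]) -> ConfigTree:
    """Deep merge, lowest precedence first; scalars and lists replace,
    subtrees merge recursively; provenance records the winning source."""
    merged = ConfigTree(source="merged")
    for src in sources:
        _merge_into(merged.data, src.data, merged.provenance, src, "")
    return merged


def _merge_into(dst: dict, src: dict, provenance: dict, source_tree: ConfigTree, prefix: str) -> None:
    for key, value in src.items():
        path = f"{prefix}.{key}" if prefix else key
        if isinstance(value, dict) and isinstance(dst.get(key), dict):
            _merge_into(dst[key], value, provenance, source_tree, path)
        elif isinstance(value, dict):
            dst[key] = {}
            _merge_into(dst[key], value, provenance, source_tree, path)
        else:
            dst[key] = value if not isinstance(value, list) else list(value)
            provenance[path] = source_tree.provenance.get(path, source_tree.source)


def load_config_file(path: str | Path, _seen: tuple = ()) -> ConfigTree:
    """Parse a .conf or .json file, resolving includes depth-first.

    Included files merge at lower precedence than the including file.
    Include cycles raise a configuration error naming the cycle.
    """
    path = Path(path)
    resolved = path.resolve()
    if resolved in _seen:
        cycle = " -> ".join(str(p) for p in _seen + (resolved,))
        raise ValueError(f"configuration include cycle: {cycle}")
    text = path.read_text()
    if path.suffix == ".json":
        tree = parse_json_config(text, source=str(path))
    else:
        tree = parse_conf(text, source=str(path))
    if not tree.includes:
        return tree
    sources = []
    for inc in tree.includes:
        inc_path = Path(inc)
        if not inc_path.is_absolute():
            inc_path = path.parent / inc_path
        sources.append(load_config_file(inc_path, _seen + (resolved,)))
    sources.append(tree)
    merged = merge_configs(sources)
    merged.source = str(path)
    return merged


# ---------------------------------------------------------------------------
# Track list management


@dataclass
class TrackStanza:
    """One track's configuration: unique label, store spec, display type."""

    label: str
    store: dict = field(default_factory=dict)  # e.g. {"format": "nclist", "path": ...}
    display_type: str = "feature"
    extra: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        record = {"label": self.label, "store": self.store, "type": self.display_type}
        record.update(self.extra)
        return record

    @classmethod
    def from_json(cls, record: dict) -> "TrackStanza":
        extra = {
            k: v for k, v in record.items() if k not in ("label", "store", "type")
        }
        return cls(
            label=record["label"],
            store=dict(record.get("store", {})),
            display_type=record.get("type", "feature"),
            extra=extra,
        )


def parse_track_list(text: str) -> list[TrackStanza]:
    data = json.loads(text)
    return [TrackStanza.from_json(r) for r in data.get("tracks", [])]


def emit_track_list(stanzas: list[TrackStanza]) -> str:
    """Deterministic trackList.json body (track order preserved)."""
    return (
        json.dumps(
            {"tracks": [s.to_json() for s in stanzas]}, sort_keys=True, indent=2
        )
        + "\n"
    )


def add_track(
    stanzas: list[TrackStanza], stanza: TrackStanza, overwrite: bool = False
) -> list[TrackStanza]:
    labels = [s.label for s in stanzas]
    if stanza.label in labels:
        if not overwrite:
            raise ValueError(f"track label {stanza.label!r} already present")
        return [stanza if s.label == stanza.label else s for s in stanzas]
    return stanzas + [stanza]


def remove_track(stanzas: list[TrackStanza], label: str) -> list[TrackStanza]:
    if label not in [s.label for s in stanzas]:
        raise ValueError(f"no track with label {label!r}")
    return [s for s in stanzas if s.label != label]


# ---------------------------------------------------------------------------
# Faceted track metadata


@dataclass
class TrackMetadata:
    """Facet values per track label; row order preserved for display."""

    rows: dict[str, dict[str, str]] = field(default_factory=dict)
    facets: list[str] = field(default_factory=list)


def load_metadata(source) -> TrackMetadata:
    """Load a facet table from CSV (RFC 4180 quoting).

    The label column is the first whose header matches "label"
    case-insensitively; its absence is a load error.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise ValueError("metadata CSV is empty") from None
    label_idx = next(
        (i for i, h in enumerate(header) if h.strip().lower() == "label"), None
    )
    if label_idx is None:
        raise ValueError("metadata CSV has no label column")
    facets = [h for i, h in enumerate(header) if i != label_idx]
    meta = TrackMetadata(facets=facets)
    for row in reader:
        if not row or all(not c.strip() for c in row):
            continue
        label = row[label_idx]
        meta.rows[label] = {
            header[i]: row[i] if i < len(row) else ""
            for i in range(len(header))
            if i != label_idx
        }
    return meta


def facet_filter(meta: TrackMetadata, filters: dict[str, set[str]]) -> list[str]:
    """Track labels whose row satisfies every filter (intersection across
    facets, OR within one facet's accepted value set). A missing or empty
    facet value never satisfies a filter on that facet."""
    out = []
    for label, row in meta.rows.items():
        ok = True
        for facet, accepted in filters.items():
            value = row.get(facet, "")
            if value == "" or value not in accepted:
                ok = False
                break
        if ok:
            out.append(label)
    return out
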