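"""Radix-tree name index: exact lookup and prefix autocomplete over feature,
alias and reference-sequence names.

Keys are ASCII case-folded so users can type lowercase; display names keep
their original case. The tree is path-compressed (no chain of single-child,
record-free nodes) and can be sharded: any subtree holding more records than
``shard_record_limit`` is serialized to its own JSON file keyed by its
prefix, so a static file server only transfers the shard a query touches.

Layout: ``<data_dir>/names/meta.json``, ``root.json`` and one
``shard-<encoded prefix>.json`` per externalized subtree.
"""

from __future__ import annotations

import json
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

from .core import Feature, GenomicInterval, RefSeqInfo

__all__ = [
    "NameRecord",
    "RadixNode",
    "NameIndex",
    "build_name_index",
    "records_from_features",
    "lookup_exact",
    "autocomplete",
    "DEFAULT_SHARD_RECORD_LIMIT",
]

DEFAULT_SHARD_RECORD_LIMIT = 1_000


def _fold(name: str) -> str:
    # simple ASCII case-fold; display names keep their case
    return name.lower()


@dataclass(frozen=True)
class NameRecord:
    """One searchable name pointing at a genomic location."""

    name: str
    kind: str  # feature | refseq | alias
    location: GenomicInterval
    track_label: str | None = None

    @property
    def normalized(self) -> str:
        return _fold(self.name)


@dataclass
class RadixNode:
    edge_label: str = ""
    children: dict[str, "RadixNode"] = field(default_factory=dict)
    records: list[NameRecord] = field(default_factory=list)
    shard_ref: str | None = None  # file name of an externalized subtree

    def subtree_record_count(self) -> int:
        return len(self.records) + sum(
            c.subtree_record_count() for c in self.children.values()
        )


def _insert(node: RadixNode, key: str, record: NameRecord) -> None:
    while True:
        if not key:
            node.records.append(record)
            return
        child = node.children.get(key[0])
        if child is None:
            node.children[key[0]] = RadixNode(edge_label=key, records=[record])
            return
        label = child.edge_label
        common = 0
        while common < len(label) and common < len(key) and label[common] == key[common]:
            common += 1
        if common == len(label):
            node, key = child, key[common:]
            continue
        # split the edge at the divergence point
        mid = RadixNode(edge_label=label[:common])
        child.edge_label = label[common:]
        mid.children[child.edge_label[0]] = child
        node.children[key[0]] = mid
        node, key = mid, key[common:]


class NameIndex:
    """Radix tree over normalized names, optionally backed by shard files."""

    def __init__(self, root: RadixNode | None = None, names_dir: Path | None = None):
        self.root = root if root is not None else RadixNode()
        self.names_dir = names_dir
        self.shards_opened = 0

    # -- construction ------------------------------------------------------

    def add(self, record: NameRecord) -> None:
        _insert(self.root, record.normalized, record)

    # -- shard resolution --------------------------------------------------

    def _resolve(self, node: RadixNode) -> RadixNode:
        if node.shard_ref is not None and not node.children and not node.records:
            assert self.names_dir is not None
            payload = json.loads((self.names_dir / node.shard_ref).read_text())
            loaded = _node_from_json(payload)
            node.children = loaded.children
            node.records = loaded.records
            node.shard_ref = None
            self.shards_opened += 1
        return node

    # -- queries -----------------------------------------------------------

    def lookup_exact(self, name: str) -> list[NameRecord]:
        key = _fold(name)
        node = self.root
        while key:
            child = node.children.get(key[0])
            if child is None:
                return []
            self._resolve(child)
            if not key.startswith(child.edge_label):
                return []
            key = key[len(child.edge_label):]
            node = child
        return sorted(
            node.records,
            key=lambda r: (r.track_label or "", r.location.start, r.kind),
        )

    def autocomplete(self, prefix: str, limit: int) -> list[str]:
        if limit < 1:
            raise ValueError("limit must be >= 1")
        key = _fold(prefix)
        node, remainder = self.root, key
        path = ""
        while remainder:
            child = node.children.get(remainder[0])
            if child is None:
                return []
            self._resolve(child)
            label = child.edge_label
            if len(remainder) < len(label):
                if not label.startswith(remainder):
                    return []
                path += label
                node = child
                remainder = ""
                break
            if not remainder.startswith(label):
                return []
            path += label
            remainder = remainder[len(label):]
            node = child
        out: list[str] = []
        self._walk_names(node, out, limit)
        return out[:limit]

    def _walk_names(self, node: RadixNode, out: list[str], limit: int) -> None:
        if len(out) >= limit:
            return
        self._resolve(node)
        if node.records:
            seen = set(out)
            for display in sorted({r.name for r in node.records}):
                if display not in seen and len(out) < limit:
                    out.append(display)
                    seen.add(display)
        for first in sorted(node.children):
            if len(out) >= limit:
                return
            self._walk_names(node.children[first], out, limit)

    def all_records(self) -> list[NameRecord]:
        out: list[NameRecord] = []

        def rec(node: RadixNode) -> None:
            self._resolve(node)
            out.extend(node.records)
            for first in sorted(node.children):
                rec(node.children[first])

        rec(self.root)
        return out

    # -- persistence --------------------------------------------------------

    def save(self, data_dir: str | Path, shard_record_limit: int = DEFAULT_SHARD_RECORD_LIMIT) -> Path:
        names_dir = Path(data_dir) / "names"
        names_dir.mkdir(parents=True, exist_ok=True)
        shards: list[str] = []

        def child_payload(child: RadixNode, prefix: str) -> dict:
            full = prefix + child.edge_label
            if child.subtree_record_count() > shard_record_limit:
                fname = "shard-" + urllib.parse.quote(full, safe="") + ".json"
                body = _node_to_json(child, child_payload, prefix=full)
                body["edge_label"] = child.edge_label
                (names_dir / fname).write_text(json.dumps(body, sort_keys=True))
                shards.append(fname)
                return {"edge_label": child.edge_label, "shard_ref": fname}
            return _node_to_json(child, child_payload, prefix=full)

        root_payload = _node_to_json(self.root, child_payload, prefix="")
        (names_dir / "root.json").write_text(json.dumps(root_payload, sort_keys=True))
        (names_dir / "meta.json").write_text(
            json.dumps(
                {"shard_record_limit": shard_record_limit, "shards": sorted(shards)},
                sort_keys=True,
                indent=1,
            )
            + "\n"
        )
        return names_dir

    @classmethod
    def load(cls, data_dir: str | Path) -> "NameIndex":
        names_dir = Path(data_dir) / "names"
        root = _node_from_json(json.loads((names_dir / "root.json").read_text()))
        return cls(root=root, names_dir=names_dir)


def _node_to_json(node: RadixNode, child_fn, prefix: str = "") -> dict:
    return {
        "edge_label": node.edge_label,
        "records": [
            {
                "name": r.name,
                "kind": r.kind,
                "track": r.track_label,
                "loc": [r.location.seq_id, r.location.start, r.location.end, r.location.strand],
            }
            for r in node.records
        ],
        "children": {
            first: child_fn(node.children[first], prefix)
            for first in sorted(node.children)
        },
    }


def _node_from_json(payload: dict) -> RadixNode:
    node = RadixNode(edge_label=payload.get("edge_label", ""))
    if "shard_ref" in payload:
        node.shard_ref = payload["shard_ref"]
        return node
    node.records = [
        NameRecord(
            name=r["name"],
            kind=r["kind"],
            track_label=r["track"],
            location=GenomicInterval(*r["loc"]),
        )
        for r in payload.get("records", [])
    ]
    node.children = {
        first: _node_from_json(sub) for first, sub in payload.get("children", {}).items()
    }
    return node


def records_from_features(
    features: list[Feature], track_label: str
) -> list[NameRecord]:
    """Name and Alias records for every named feature in a forest."""
    records: list[NameRecord] = []
    for root in features:
        for f in root.walk():
            if f.name is not None:
                records.append(
                    NameRecord(f.name, "feature", f.interval, track_label)
                )
            elif f.id is not None:
                records.append(NameRecord(f.id, "feature", f.interval, track_label))
            for alias in f.attributes.get("Alias", []):
                records.append(NameRecord(alias, "alias", f.interval, track_label))
    return records


def build_name_index(
    records: list[NameRecord],
    refseqs: list[RefSeqInfo] | None = None,
) -> NameIndex:
    """Build the radix tree; reference-sequence names are always included."""
    index = NameIndex()
    for info in refseqs or []:
        index.add(
            NameRecord(info.name, "refseq", GenomicInterval(info.name, 0, info.length))
        )
        for alias in info.aliases:
            index.add(
                NameRecord(alias, "alias", GenomicInterval(info.name, 0, info.length))
            )
    for record in records:
        index.add(record)
    return index


def lookup_exact(index: NameIndex, name: str) -> list[NameRecord]:
    return index.lookup_exact(name)


def autocomplete(index: NameIndex, prefix: str, limit: int) -> list[str]:
    return index.autocomplete(prefix, limit)
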