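"""Configuration merging and faceted track-metadata filtering.

Configuration can come from several places — included files, per-dataset
files, top-level files, an embedding application, URL query parameters —
merged lowest-precedence first, key by key, with provenance recorded.
"""

from trackkit.config import (
    facet_filter,
    load_metadata,
    merge_configs,
    parse_conf,
    parse_json_config,
    parse_query_params,
)

datadir = parse_conf(
    "[tracks.genes]\n"
    "key = Gene models\n"
    "style = function(feature) { return feature.score > 5 ? 'bold' : 'plain'; }\n",
    source="data/tracks.conf",
)
toplevel = parse_json_config('{"theme": "light", "tracks": {"genes": {"key": "Genes"}}}',
                             source="site.json")
url = parse_query_params("theme=dark")

merged = merge_configs([datadir, toplevel, url])
print("track key :", merged.get("tracks.genes.key"), "   <- top-level file wins")
print("theme     :", merged.get("theme"), "       <- URL parameter wins")
print("style     :", merged.get("tracks.genes.style")[:30], "... (callback kept verbatim, never run)")
print("provenance:", merged.provenance["theme"])

meta = load_metadata(
    "label,technique,lab\n"
    "chip_k4,ChIP-seq,Snyder\n"
    "chip_k27,ChIP-seq,Ren\n"
    "rna_1,RNA-seq,Snyder\n"
)
print("\nChIP-seq tracks:", facet_filter(meta, {"technique": {"ChIP-seq"}}))
print("ChIP-seq AND Snyder:",
      facet_filter(meta, {"technique": {"ChIP-seq"}, "lab": {"Snyder"}}))
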