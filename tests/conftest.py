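import io
import random

import pytest

from trackkit import fixtures, refseq
from trackkit.core import Feature


@pytest.fixture
def rng():
    return random.Random(20_240_901)


@pytest.fixture
def small_spec():
    return fixtures.FixtureSpec(seed=7, n_refseqs=1, refseq_length=10_000, n_genes=30)


@pytest.fixture
def genome_catalog(tmp_path, small_spec):
    """A chunked sequence store over the small fixture genome."""
    fasta = fixtures.make_genome(small_spec)
    return refseq.import_fasta(io.StringIO(fasta), tmp_path, chunk_size=1_000)


@pytest.fixture
def genome_sequence(small_spec):
    return fixtures.genome_sequences(small_spec)["ctg01"]


def random_features(rng, n, seq_id="ctg01", span=10_000):
    ivs = fixtures.make_random_intervals(rng, n, seq_id=seq_id, span=span)
    return [Feature(interval=iv, id=f"f{i}") for i, iv in enumerate(ivs)]


def brute_force_overlap(features, start, end):
    return sorted(
        ((f.start, f.end) for f in features if f.start < end and start < f.end)
    )


def feature_forest_key(f: Feature):
    """Semantic identity of a feature tree (order-insensitive attributes)."""
    return (
        f.seq_id,
        f.start,
        f.end,
        f.strand,
        f.type,
        f.id,
        f.name,
        f.score,
        f.phase,
        tuple(sorted((k, tuple(v)) for k, v in f.attributes.items())),
        tuple(sorted(feature_forest_key(s) for s in f.subfeatures)),
    )
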