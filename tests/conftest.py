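import itertools

import pytest

import magrefine as mg


@pytest.fixture(scope="session")
def marker_sets():
    """The shipped bacterial (120) and archaeal (53) sets."""
    return mg.default_marker_sets()


@pytest.fixture(scope="session")
def small_marker_sets():
    """Down-scaled domain sets for fast randomized refinement instances."""
    return {
        "bacteria": mg.MarkerSet("bacteria", frozenset(f"B{i:02d}" for i in range(40))),
        "archaea": mg.MarkerSet("archaea", frozenset(f"A{i:02d}" for i in range(20))),
    }


@pytest.fixture(scope="session")
def pipeline():
    """Chain: records + hits -> merged collection -> refinement result."""

    def _run(binsets, hits, sets, merge_params=None, refine_params=None,
             return_collections=False):
        annotations = mg.select_best_hits(hits)
        collection = mg.BinCollection.from_records(itertools.chain.from_iterable(binsets))
        all_ids = frozenset().union(*(m.marker_ids for m in sets.values()))
        genes = mg.contig_marker_genes(annotations, all_ids)
        merged = mg.propose_hybrids(collection, genes, merge_params or mg.MergeParams())
        result = mg.refine(merged, annotations, sets, refine_params or mg.RefinementParams())
        if return_collections:
            return result, collection, merged, annotations
        return result

    return _run


@pytest.fixture(scope="session")
def standard_run(pipeline, marker_sets):
    """The canonical 20-genome / 3-binner benchmark, refined once."""
    truth, models, binsets, hits = mg.standard_fixture(seed=42)
    result, collection, merged, annotations = pipeline(
        binsets, hits, marker_sets, return_collections=True)
    return {
        "truth": truth, "models": models, "binsets": binsets, "hits": hits,
        "result": result, "collection": collection, "merged": merged,
        "annotations": annotations,
    }
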