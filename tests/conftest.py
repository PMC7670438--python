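import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from xeno.config import RunConfig
from xeno.pipeline import run_pipeline
from xeno.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """The packaged demo bundle at its default (noise-free) settings."""
    return simulate_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def demo_report(tmp_path_factory):
    """A full pipeline run on the synthetic demo configuration."""
    outdir = tmp_path_factory.mktemp("demo")
    config = RunConfig(seed=1, output_dir=str(outdir))
    report = run_pipeline(config)
    return report


@pytest.fixture(scope="session")
def screen_classifications(bundle):
    """Screen + triage of the demo bundle, with a truth lookup for queries.

    Returns (classifications, counts, truth_of) where ``truth_of`` maps a
    query id to its generator truth origin.
    """
    from xeno.records import ReadSet, SequenceRecord
    from xeno.screen import Panels, classify_hits, collapse_unique_reads, local_search
    from xeno.simulate import OUTGROUP_TIPS

    config = RunConfig(seed=1)
    focal = bundle.config.focal_host
    transcripts = sorted(bundle.host_genes[focal].values(), key=lambda r: r.id)
    all_reads = [r for lib in bundle.read_libraries for r in lib]
    merged = ReadSet(reads=all_reads, library_size=len(all_reads))
    unique = collapse_unique_reads(merged)
    read_queries = [SequenceRecord(id=i, seq=s, taxon=focal)
                    for i, s in zip(unique.ids, unique.sequences)]
    queries = transcripts + read_queries
    subjects = sorted(bundle.donor_genes[bundle.config.focal_donor].values(),
                      key=lambda r: r.id)
    hits = local_search(queries, subjects, config.screen)
    panels = Panels(
        outgroup_plant=[rec for t in OUTGROUP_TIPS
                        for rec in bundle.host_genes[t].values()],
        host_assembly=transcripts,
        donor=subjects,
    )
    classifications, counts = classify_hits(hits, queries, panels,
                                            config.triage, config.screen)

    read_origin = dict(zip(bundle.read_truth.id, bundle.read_truth.origin))
    hgt_genes = {e.gene_id for e in bundle.config.hgt_events}

    def truth_of(query_id: str) -> str:
        if query_id in read_origin:
            return read_origin[query_id]
        gene = query_id.split("|")[0]
        if gene in hgt_genes:
            return "hgt"
        return "conserved" if gene.startswith("conserved") else "vertical"

    return classifications, counts, truth_of
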