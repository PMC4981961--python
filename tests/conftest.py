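"""Shared fixtures: one synthetic study and its pipeline stages, built once."""

from __future__ import annotations

import pytest

from miralga.annotate import annotate_cascade
from miralga.mapping import map_reads
from miralga.pipeline import PipelineConfig, run_pipeline
from miralga.qc import clean_reads
from miralga.synthio import SimConfig, make_genome, make_references, simulate_reads


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: genome, raw reads, references, truth."""
    cfg = SimConfig(seed=1)
    contigs, truth = make_genome(cfg)
    raw = simulate_reads(contigs, truth, cfg)
    refs = make_references(cfg, truth)
    return {"cfg": cfg, "contigs": contigs, "truth": truth, "raw": raw,
            "refs": refs}


@pytest.fixture(scope="session")
def stages(study):
    """QC, mapping and annotation intermediates of the default study."""
    unique, labels, report = clean_reads(study["raw"])
    hits, msum = map_reads(unique, study["contigs"])
    hits_by_read: dict[str, list] = {}
    for h in hits:
        hits_by_read.setdefault(h.read_id, []).append(h)
    ann, ann_summary = annotate_cascade(unique, study["refs"].ncrna,
                                        study["refs"].mature_db)
    return {"unique": unique, "labels": labels, "report": report,
            "hits": hits, "hits_by_read": hits_by_read, "msum": msum,
            "ann": ann, "ann_summary": ann_summary}


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full end-to-end run of the pipeline at the default seed."""
    out = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(PipelineConfig(seed=1, out_dir=str(out)))
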