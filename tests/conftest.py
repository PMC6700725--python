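from __future__ import annotations

import numpy as np
import pytest

from venomalt.annotation_model import ExonInterval, GeneLocus, TranscriptModel
from venomalt.synthetic_data import (
    CountsPlan,
    EventPlan,
    EvidencePlan,
    FixtureSpec,
    make_annotation_fixture,
    make_counts_fixture,
    make_evidence_fixture,
)


def make_tx(tid, exons, strand="+", chrom="chr1", gene="G1", source="reference"):
    return TranscriptModel(
        tid,
        gene,
        tuple(ExonInterval(chrom, s, e, strand) for s, e in exons),
        source=source,
    )


def make_locus(gene_id, chains, strand="+", chrom="chr1"):
    return GeneLocus(
        gene_id,
        [
            make_tx(f"{gene_id}.t{i + 1}", exons, strand, chrom, gene_id)
            for i, exons in enumerate(chains)
        ],
    )


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def annotation_fixture(default_spec):
    return make_annotation_fixture(default_spec.event_plans, seed=default_spec.seed)


@pytest.fixture(scope="session")
def seven_event_fixture():
    plans = (EventPlan(("AFE", "A5SS", "A3SS", "EXON_SKIP", "MXE", "INTRON_RETENTION", "ALE")),)
    return make_annotation_fixture(plans, seed=11)


@pytest.fixture(scope="session")
def evidence_fixture(default_spec):
    return make_evidence_fixture(default_spec.evidence, seed=default_spec.seed)


@pytest.fixture(scope="session")
def counts_fixture(default_spec):
    return make_counts_fixture(default_spec.counts, seed=default_spec.seed)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
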