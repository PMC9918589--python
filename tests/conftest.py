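"""Shared fixtures: synthetic alignments + toy annotation databases.

Everything is generated at test time from seeded specs; the session-scoped
bundle (600-kb contig, 30x background, one engineered heterozygous 40-kb
deletion) is shared by the evidence, workflow and acceptance tests.
"""

from dataclasses import dataclass
from pathlib import Path

import pytest

from cnvtriage.annotations import AnnotationSet, load_annotation_set
from cnvtriage.core import CnvCall, CnvType, GenomicInterval
from cnvtriage.fixtures import (
    default_annotation_set,
    default_fixture_spec,
    make_reference_fasta,
    make_toy_annotations,
    simulate_alignments_with_cnv,
)


@dataclass
class SimBundle:
    root: Path
    reference: Path
    bam: Path
    annodir: Path
    annotation: AnnotationSet
    pathogenic_cnv: CnvCall
    spec: object


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory) -> SimBundle:
    """Default synthetic study: engineered HI-containing het deletion at
    chrT:300000-340000 with 12 discordant pairs and 6 split reads."""
    root = tmp_path_factory.mktemp("sim")
    spec = default_fixture_spec(seed=1)
    reference = make_reference_fasta(spec, root / "reference.fa")
    bam = simulate_alignments_with_cnv(spec, reference, root / "sample.bam")
    annodir = make_toy_annotations(default_annotation_set(), root / "annotations")
    annotation = load_annotation_set(annodir)
    cnv = CnvCall(GenomicInterval("chrT", 300_000, 340_000), CnvType.DELETION, "S1")
    return SimBundle(root, reference, bam, annodir, annotation, cnv, spec)


@pytest.fixture()
def toy_annotation() -> AnnotationSet:
    return default_annotation_set()
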