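from types import SimpleNamespace

import pytest
from pyfaidx import Fasta

from agscan.annotation_db import IntronDB
from agscan.simulate import (default_fixture, make_variant_set,
                             make_worked_variants_fixture)


def load_fixture(fixture, outdir):
    """Write a Fixture to disk and load it back through the file formats."""
    paths = fixture.write(outdir)
    vcf, truth = make_variant_set(fixture, outdir)
    genome = Fasta(str(paths["fasta"]))
    db = IntronDB.build(paths["gtf"], paths["bp"],
                        canonical_path=paths["canonical"], genome=genome)
    return SimpleNamespace(fixture=fixture, paths=paths, vcf=vcf,
                           truth_path=truth, genome=genome, db=db)


@pytest.fixture(scope="session")
def fx(tmp_path_factory):
    """Default random fixture: every mechanism class planted plus negatives."""
    return load_fixture(default_fixture(seed=1), tmp_path_factory.mktemp("fx"))


@pytest.fixture(scope="session")
def worked(tmp_path_factory):
    """Hand-crafted miniatures of the published worked-case geometries."""
    return load_fixture(make_worked_variants_fixture(),
                        tmp_path_factory.mktemp("worked"))
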