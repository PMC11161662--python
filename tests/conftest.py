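import numpy as np
import pandas as pd
import pytest

from m6abasemap.annotation import TranscriptModel
from m6abasemap.simulate import SimConfig, write_simulation


def make_calls(records):
    """Build a site-call table from (chrom, pos, strand, fraction[, passed]) tuples."""
    rows = []
    for rec in records:
        chrom, pos, strand, fraction = rec[:4]
        passed = rec[4] if len(rec) > 4 else True
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "depth": 100,
                "mut_count": 10,
                "motif": "GGACT",
                "raw_rate": 0.1,
                "fraction": fraction,
                "passed": passed,
                "fail_reason": "none" if passed else "low_depth",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "depth", "mut_count", "motif",
            "raw_rate", "fraction", "passed", "fail_reason",
        ],
    ).astype({"passed": bool})


@pytest.fixture
def simple_transcript():
    """Single-exon plus-strand coding transcript: exon [0,300), CDS [50,250)."""
    return TranscriptModel("t1", "g1", "chr1", "+", [(0, 300)], 50, 250)


@pytest.fixture
def two_exon_minus():
    """Minus-strand two-exon transcript; exon order is 5'->3' in transcript space."""
    return TranscriptModel("t2", "g2", "chr1", "-", [(500, 700), (100, 300)], 50, 350)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A small end-to-end synthetic data set shared across tests."""
    cfg = SimConfig(seed=7, n_genes=15)
    outdir = tmp_path_factory.mktemp("sim")
    bundle = write_simulation(cfg, outdir)
    bundle["outdir"] = outdir
    bundle["config"] = cfg
    return bundle
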