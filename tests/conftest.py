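import numpy as np
import pandas as pd
import pytest

from kincrac.types import Alignment, GeneAnnotation, ReadRecord, TimeCourseMatrix

TIMEPOINTS = [0.0, 1.0, 2.0, 4.0, 8.0, 14.0, 20.0]


def make_read(read_id, chrom="chrI", start=0, end=10, strand="+", umi="AAAAAA",
              seq=None, clip=""):
    length = end - start
    return ReadRecord(
        read_id=read_id,
        sequence=seq if seq is not None else "ACGT" * (length // 4 + 1),
        umi=umi,
        alignments=[Alignment(chrom=chrom, start=start, end=end, strand=strand,
                              soft_clip_3prime=clip)],
    )


def make_timecourse(values_by_gene, timepoints=None, conditions=("control", "treated"),
                    replicates=(1, 2)):
    """Build a TimeCourseMatrix from {gene: constant or per-sample dict}.

    ``values_by_gene[gene]`` is either a scalar (every sample gets that
    series value at all timepoints) or a mapping (condition, replicate)
    -> list of values over the timepoints.
    """
    timepoints = timepoints or TIMEPOINTS
    rows = []
    for gene, spec in values_by_gene.items():
        for cond in conditions:
            for rep in replicates:
                if isinstance(spec, dict):
                    series = spec[(cond, rep)]
                else:
                    series = [spec] * len(timepoints)
                for t, v in zip(timepoints, series):
                    rows.append((gene, cond, rep, t, float(v)))
    return TimeCourseMatrix(
        pd.DataFrame(rows, columns=["gene_id", "condition", "replicate",
                                    "timepoint_min", "value"])
    )


@pytest.fixture
def plus_gene():
    return GeneAnnotation(gene_id="GPLUS", chrom="chrI", strand="+", tss=500,
                          end3=1500)


@pytest.fixture
def minus_gene():
    return GeneAnnotation(gene_id="GMINUS", chrom="chrI", strand="-", tss=1499,
                          end3=499)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
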