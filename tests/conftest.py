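import numpy as np
import pytest

from mrscreen.gwas_io import HarmonizedInstrument, VariantAssociation


def make_variant(snp_id, beta, se, pvalue=None, ea="A", oa="G", **kw):
    """VariantAssociation with the p-value derived from beta/se by default."""
    from scipy import stats

    if pvalue is None:
        pvalue = float(max(2 * stats.norm.sf(abs(beta) / se), 5e-324))
    return VariantAssociation(
        snp_id=snp_id, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, pvalue=pvalue, **kw,
    )


def make_instruments(bx, sx, by, sy, ids=None):
    ids = ids or [f"snp_{j}" for j in range(len(bx))]
    return [
        HarmonizedInstrument(
            snp_id=i, beta_exposure=float(a), se_exposure=float(b),
            beta_outcome=float(c), se_outcome=float(d),
        )
        for i, a, b, c, d in zip(ids, bx, sx, by, sy)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def five_instruments(rng):
    """Well-behaved instrument set with a positive causal effect of 0.3."""
    bx = rng.uniform(0.05, 0.15, 5)
    sx = np.full(5, 0.005)
    sy = np.full(5, 0.02)
    by = 0.3 * bx + rng.normal(0, 0.005, 5)
    return make_instruments(bx, sx, by, sy)


@pytest.fixture
def summary_tsv(tmp_path):
    """Three-row well-formed TSV in the canonical dialect."""
    path = tmp_path / "stats.tsv"
    path.write_text(
        "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"
        "rs1\t1\t1000\tA\tG\t0.3\t0.05\t0.006\t7.7e-17\t100000\n"
        "rs2\t2\t2000\tC\tT\t0.2\t-0.04\t0.005\t1.3e-15\t100000\n"
        "rs3\t3\t3000\tG\tA\t0.45\t0.03\t0.005\t1.97e-09\t100000\n"
    )
    return path
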