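import numpy as np
import pytest

from tailhmm.hmm_core import NONTAIL, TAIL, TailHmm

# two genomes, 2 and 3 CDS; the second CDS of PHG001 has no product
GENBANK_TWO_RECORDS = """\
LOCUS       PHG001                   240 bp    DNA     linear   PHG 01-JAN-2024
DEFINITION  synthetic test phage A.
ACCESSION   PHG001
VERSION     PHG001
FEATURES             Location/Qualifiers
     source          1..240
     CDS             1..90
                     /protein_id="PHG001_p0"
                     /product="tail fibre protein"
     CDS             complement(101..190)
                     /protein_id="PHG001_p1"
ORIGIN
        1 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
       61 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
      121 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
      181 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
//
LOCUS       PHG002                   240 bp    DNA     linear   PHG 01-JAN-2024
DEFINITION  synthetic test phage B.
ACCESSION   PHG002
VERSION     PHG002
FEATURES             Location/Qualifiers
     source          1..240
     CDS             1..60
                     /protein_id="PHG002_p0"
                     /product="major capsid protein"
     CDS             71..130
                     /protein_id="PHG002_p1"
                     /product="tape measure protein"
     CDS             141..200
                     /protein_id="PHG002_p2"
                     /product="hypothetical protein"
ORIGIN
        1 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
       61 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
      121 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
      181 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
//
"""

# 5 data rows, 2 below 1e-4 (hmmscan --domtblout column layout)
DOMTBL_FIVE_ROWS = """\
# target name        accession   tlen query name           accession   qlen   E-value  score  bias ...
Phage_T_dom          PF90001.3    200 PHG001_p0            -            300   1.2e-06  150.0   0.0   1   1   1.2e-06   1.2e-06  150.0   0.0 1 200 1 200 1 200 0.95 tail domain
Phage_T_dom          PF90002.1    200 PHG001_p0            -            300   3.0e-03   20.0   0.0   1   1   3.0e-03   3.0e-03   20.0   0.0 1 200 1 200 1 200 0.95 weak hit
Capsid_dom           PF10001.5    200 PHG002_p0            -            300   5.0e-12  210.0   0.0   1   1   5.0e-12   5.0e-12  210.0   0.0 1 200 1 200 1 200 0.95 capsid domain
Capsid_dom           PF10001.5    200 PHG002_p2            -            300   2.0e-04   15.0   0.0   1   1   2.0e-04   2.0e-04   15.0   0.0 1 200 1 200 1 200 0.95 weak hit
Junk_dom             PF10002.2    200 PHG002_p1            -            300   9.9e-01    1.0   0.0   1   1   9.9e-01   9.9e-01    1.0   0.0 1 200 1 200 1 200 0.95 junk
"""


@pytest.fixture
def genbank_file(tmp_path):
    p = tmp_path / "two_phages.gbk"
    p.write_text(GENBANK_TWO_RECORDS)
    return p


@pytest.fixture
def domtbl_file(tmp_path):
    p = tmp_path / "hits.domtbl"
    p.write_text(DOMTBL_FIVE_ROWS)
    return p


@pytest.fixture
def toy_corpus():
    """The 2-genome hand corpus with known count ratios."""
    return [
        [("d1", TAIL), ("d2", TAIL), ("d3", NONTAIL), ("d4", NONTAIL)],
        [("d3", NONTAIL), ("d1", TAIL)],
    ]


def random_model(rng: np.random.Generator, n_symbols: int = 5,
                 epsilon: float = 1e-4) -> TailHmm:
    """A random valid two-state model over symbols s0..s{n-1}."""
    symbols = [f"s{i}" for i in range(n_symbols)]
    pi = rng.dirichlet([1.0, 1.0])
    A = np.vstack([rng.dirichlet([1.0, 1.0]) for _ in range(2)])
    B = {}
    for state in (TAIL, NONTAIL):
        w = rng.dirichlet(np.ones(n_symbols))
        B[state] = {s: float(wi) * (1 - epsilon) for s, wi in zip(symbols, w)}
    return TailHmm(pi=pi, A=A, B=B, alphabet=frozenset(symbols), epsilon=epsilon)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
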