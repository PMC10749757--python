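import numpy as np
import pandas as pd
import pytest

from crossgex import ExpressionTable, IdMap, load_homologene


@pytest.fixture
def toy_expression() -> ExpressionTable:
    """Two genes, two species, two tissues, two samples each (VST-ish)."""
    rows = []
    vals = iter(np.linspace(5.0, 8.0, 16))
    for gene in ("geneA", "geneB"):
        for sp in ("human", "mouse"):
            for tissue in ("liver", "brain"):
                for sample in ("s1", "s2"):
                    rows.append((gene, sp, tissue, sample, next(vals)))
    df = pd.DataFrame(rows, columns=["gene_id", "species", "tissue",
                                     "sample_id", "value"])
    return ExpressionTable(df, scale="vst")


@pytest.fixture
def expression_tsv(tmp_path, toy_expression):
    path = tmp_path / "expr.tsv"
    toy_expression.data.to_csv(path, sep="\t", index=False)
    return path


HOMOLOGENE_LINES = [
    # group 1: human/mouse/rat one-to-one
    "1\t9606\t100\tGNA1\t11\tNP_01",
    "1\t10090\t200\tGna1\t12\tNP_02",
    "1\t10116\t300\tGna1\t13\tNP_03",
    # group 2: human + zebrafish paralog expansion (1:2)
    "2\t9606\t110\tGNB1\t21\tNP_04",
    "2\t7955\t210\tgnb1a\t22\tNP_05",
    "2\t7955\t211\tgnb1b\t23\tNP_06",
    # group 3: human only
    "3\t9606\t120\tGNC1\t31\tNP_07",
]


@pytest.fixture
def homologene_file(tmp_path):
    path = tmp_path / "homologene.data"
    path.write_text("\n".join(HOMOLOGENE_LINES) + "\n")
    return path


@pytest.fixture
def ortholog_table(homologene_file):
    return load_homologene(homologene_file)


@pytest.fixture
def toy_idmap() -> IdMap:
    df = pd.DataFrame(
        [
            ("human", "ENSG01", "100", "GNA1"),
            ("human", "ENSG02", "110", "GNB1"),
            ("human", "ENSG03", "", "NOENTREZ"),
            ("human", "ENSG04", "7", "DUP"),
            ("human", "ENSG05", "8", "DUP"),
            ("mouse", "ENSMUSG01", "200", "Gna1"),
        ],
        columns=["species", "ensembl_id", "entrez_id", "symbol"],
    )
    return IdMap(df)
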