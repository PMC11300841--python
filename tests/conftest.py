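"""Shared fixtures: fixture lexicons and worked-example sentences.

The worked examples are published miRNA-disease assertions (Alzheimer's
disease, Parkinson's disease and epilepsy abstracts) whose bolded miRNA
mentions have known miRBase mature accessions; they exercise detection,
normalization and pair enumeration end to end.
"""

import pytest

from mirtext import synthetic

# (sentence, pmid, [(bold mention, expected MIMAT accession), ...])
WORKED_EXAMPLES = [
    (
        "The miR-501-3p, miR-502-3p, and miR-877-5p were identified as "
        "potential synaptosomal miRNAs upregulated with disease progression "
        "based on AD Braak stages.",
        "36454178",
        [("miR-501-3p", "MIMAT0004774"),
         ("miR-502-3p", "MIMAT0004775"),
         ("miR-877-5p", "MIMAT0004949")],
    ),
    (
        "Elevated miR-133b and miR-221-3p distinguished PD from controls "
        "with 84.8% sensitivity and 88.9% specificity.",
        "34315950",
        [("miR-133b", "MIMAT0000770"),
         ("miR-221-3p", "MIMAT0000278")],
    ),
    (
        "Overexpression of let-7b inhibited hippocampal glial cell "
        "activation, inflammatory response and epileptic seizures by "
        "targeting Stat3.",
        "32648622",
        [("let-7b", "MIMAT0000063")],
    ),
    (
        "LncRNA H19 could competitively bind to let-7b to promote "
        "hippocampal glial cell activation and epileptic seizures by "
        "targeting Stat3 in a rat model of TLE.",
        "32648622",
        [("let-7b", "MIMAT0000063")],
    ),
]


@pytest.fixture(scope="session")
def lexicons():
    return synthetic.generate_lexicons()


@pytest.fixture(scope="session")
def mirbase_lexicon(lexicons):
    return lexicons[0]


@pytest.fixture(scope="session")
def mesh_lexicon(lexicons):
    return lexicons[1]
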