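import numpy as np
import pytest

from xenoscan.homology import HitTable, hit_table_from_records
from xenoscan.taxonomy import TaxonomyTable, taxonomy_from_rows

# synthetic clade layout shared by many tests:
# root(1) -> Animals(2), Bacteria(3), Fungi(4), Viridiplantae(5)
# Animals -> SelfClade(20) -> speciesA(21); Animals -> animal taxa 101..103
# donor leaves: 201..203 (bacteria), 301 (fungi), 401 (plants)
TAX_ROWS = [
    (1, 1, "no rank", "root"),
    (2, 1, "kingdom", "Animals"),
    (3, 1, "superkingdom", "Bacteria"),
    (4, 1, "kingdom", "Fungi"),
    (5, 1, "kingdom", "Viridiplantae"),
    (20, 2, "subfamily", "SelfClade"),
    (21, 20, "species", "speciesA"),
    (101, 2, "species", "animal_1"),
    (102, 2, "species", "animal_2"),
    (103, 2, "species", "animal_3"),
    (201, 3, "species", "bact_1"),
    (202, 3, "species", "bact_2"),
    (203, 3, "species", "bact_3"),
    (301, 4, "species", "fung_1"),
    (401, 5, "species", "plant_1"),
]

KINGDOMS = {"bacteria": 3, "fungi": 4, "viridiplantae": 5}


@pytest.fixture(scope="session")
def taxonomy() -> TaxonomyTable:
    return taxonomy_from_rows(TAX_ROWS)


def make_hits(rows) -> HitTable:
    """rows: (query, subject, taxids, bitscore[, identity, length, evalue, qcov])."""
    records = []
    for row in rows:
        q, s, taxids, bits = row[:4]
        ident = row[4] if len(row) > 4 else 50.0
        length = row[5] if len(row) > 5 else 200
        evalue = row[6] if len(row) > 6 else 1e-30
        qcov = row[7] if len(row) > 7 else 80.0
        records.append({
            "query_id": q, "subject_id": s, "pct_identity": ident,
            "aln_length": length, "evalue": evalue, "bitscore": bits,
            "subject_taxids": list(taxids), "query_coverage": qcov,
        })
    return hit_table_from_records(records)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
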