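"""Gene-catalog ingestion, enzyme-profile aggregation, differential selection."""

import pandas as pd
import pytest

from rhizoscope._errors import FormatError, ValidationError
from rhizoscope.catalog import (
    GeneCatalog,
    build_enzyme_profile,
    read_gene_catalog,
    select_differential,
)


def write_tsv(path, text):
    path.write_text(text)
    return path


DESIGN = "sample_id\tenvironment\treplicate\ns1\troot\t1\ns2\troot\t2\ns3\tsoil\t1\ns4\tsoil\t2\n"


@pytest.fixture
def design_file(tmp_path):
    return write_tsv(tmp_path / "design.tsv", DESIGN)


class TestReadGeneCatalog:
    def test_identity_ingest(self, tmp_path, design_file):
        cat_file = write_tsv(
            tmp_path / "cat.tsv",
            "gene_id\tsample_id\tread_count\tko_id\ttaxon\n"
            "g1\ts1\t5\tK00001\tRhizobiales\n"
            "g2\ts1\t3\tK00002\tBurkholderiales\n"
            "g1\ts3\t2\tK00001\tRhizobiales\n",
        )
        gc = read_gene_catalog(cat_file, design_file)
        assert len(gc.records) == 3
        assert set(gc.records["sample_id"]) == {"s1", "s3"}

    def test_unknown_sample_rejected(self, tmp_path, design_file):
        cat_file = write_tsv(
            tmp_path / "cat.tsv",
            "gene_id\tsample_id\tread_count\tko_id\ttaxon\ng1\tsX\t5\tK00001\tRhizobiales\n",
        )
        with pytest.raises(ValidationError, match="sX"):
            read_gene_catalog(cat_file, design_file)

    def test_duplicate_rows_summed(self, tmp_path, design_file):
        cat_file = write_tsv(
            tmp_path / "cat.tsv",
            "gene_id\tsample_id\tread_count\tko_id\ttaxon\n"
            "g1\ts1\t2\tK00001\tRhizobiales\n"
            "g1\ts1\t3\tK00001\tRhizobiales\n",
        )
        gc = read_gene_catalog(cat_file, design_file)
        assert len(gc.records) == 1
        assert gc.records["read_count"].iloc[0] == 5

    def test_missing_column_named(self, tmp_path, design_file):
        cat_file = write_tsv(
            tmp_path / "cat.tsv", "gene_id\tsample_id\tko_id\ttaxon\ng1\ts1\tK1\tt\n"
        )
        with pytest.raises(FormatError, match="read_count"):
            read_gene_catalog(cat_file, design_file)

    def test_negative_count_rejected(self, tmp_path, design_file):
        cat_file = write_tsv(
            tmp_path / "cat.tsv",
            "gene_id\tsample_id\tread_count\tko_id\ttaxon\ng1\ts1\t-2\tK00001\tt\n",
        )
        with pytest.raises(ValidationError, match="negative"):
            read_gene_catalog(cat_file, design_file)

    def test_empty_taxon_becomes_sentinel(self, tmp_path, design_file):
        cat_file = write_tsv(
            tmp_path / "cat.tsv",
            "gene_id\tsample_id\tread_count\tko_id\ttaxon\ng1\ts1\t5\tK00001\t\n",
        )
        gc = read_gene_catalog(cat_file, design_file)
        assert gc.records["taxon"].iloc[0] == "unassigned"


def _catalog(rows):
    records = pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "read_count", "ko_id", "taxon"]
    )
    design = pd.DataFrame(
        [("s1", "root", 1), ("s2", "root", 2), ("s3", "soil", 1), ("s4", "soil", 2)],
        columns=["sample_id", "environment", "replicate"],
    )
    return GeneCatalog(records, design)


class TestBuildEnzymeProfile:
    def test_single_ec(self):
        gc = _catalog([("g1", "s1", 7, "K00001", "Rhizobiales")])
        ko2ec = pd.DataFrame({"ko_id": ["K00001"], "ec": ["1.1.1.1"]})
        profile = build_enzyme_profile(gc, ko2ec)
        assert len(profile) == 1
        assert profile["read_count"].iloc[0] == 7
        assert profile["enzyme"].iloc[0] == "1.1.1.1"

    def test_multi_ec_duplication(self):
        # a KO mapping to two ECs contributes its full count to each
        gc = _catalog([("g1", "s1", 4, "K00001", "Rhizobiales")])
        ko2ec = pd.DataFrame(
            {"ko_id": ["K00001", "K00001"], "ec": ["1.1.1.1", "2.2.2.2"]}
        )
        profile = build_enzyme_profile(gc, ko2ec)
        assert sorted(profile["enzyme"]) == ["1.1.1.1", "2.2.2.2"]
        assert list(profile["read_count"]) == [4, 4]

    def test_unmapped_ko_dropped(self):
        gc = _catalog([("g1", "s1", 4, "K99999", "Rhizobiales")])
        ko2ec = pd.DataFrame({"ko_id": ["K00001"], "ec": ["1.1.1.1"]})
        assert build_enzyme_profile(gc, ko2ec).empty

    def test_malformed_ec_rejected(self):
        gc = _catalog([("g1", "s1", 4, "K00001", "Rhizobiales")])
        ko2ec = pd.DataFrame({"ko_id": ["K00001"], "ec": ["EC-oops"]})
        with pytest.raises(ValidationError, match="EC"):
            build_enzyme_profile(gc, ko2ec)

    def test_reads_conserved_for_single_ec_kos(self):
        rows = [
            ("g1", "s1", 7, "K00001", "A"),
            ("g2", "s1", 3, "K00002", "B"),
            ("g3", "s2", 11, "K00001", "A"),
        ]
        gc = _catalog(rows)
        ko2ec = pd.DataFrame(
            {"ko_id": ["K00001", "K00002"], "ec": ["1.1.1.1", "2.2.2.2"]}
        )
        profile = build_enzyme_profile(gc, ko2ec)
        assert profile["read_count"].sum() == sum(r[2] for r in rows)


def _profile(counts):
    """counts: {(enzyme, sample): n} -> long-form profile (single taxon)."""
    rows = [(e, s, "T", n) for (e, s), n in counts.items()]
    return pd.DataFrame(rows, columns=["enzyme", "sample_id", "taxon", "read_count"])


DESIGN_DF = pd.DataFrame(
    [("s1", "root", 1), ("s2", "root", 2), ("s3", "soil", 1), ("s4", "soil", 2)],
    columns=["sample_id", "environment", "replicate"],
)


def balanced_profile(enzyme_counts):
    """enzyme_counts: {enzyme: (per-root-sample count, per-soil-sample count)};
    a 'filler' enzyme equalises library sizes across samples."""
    counts = {}
    for e, (a, b) in enzyme_counts.items():
        counts[(e, "s1")] = a
        counts[(e, "s2")] = a
        counts[(e, "s3")] = b
        counts[(e, "s4")] = b
    total_a = sum(a for a, _ in enzyme_counts.values())
    total_b = sum(b for _, b in enzyme_counts.values())
    filler = 10000
    for s, tot in (("s1", total_a), ("s2", total_a), ("s3", total_b), ("s4", total_b)):
        counts[("9.9.9.9", s)] = filler - tot
    return _profile(counts)


class TestSelectDifferential:
    def test_strong_enrichment_detected(self):
        profile = balanced_profile({"1.1.1.1": (100, 10)})
        da, db = select_differential(profile, DESIGN_DF, "root", "soil")
        assert "1.1.1.1" in da.enzymes
        assert "1.1.1.1" not in db.enzymes
        assert da.provenance == "standin"

    def test_fold_below_threshold_excluded(self):
        # fold change 1.5 never qualifies regardless of significance
        profile = balanced_profile({"1.1.1.1": (1500, 1000)})
        da, db = select_differential(profile, DESIGN_DF, "root", "soil")
        assert "1.1.1.1" not in da.enzymes and "1.1.1.1" not in db.enzymes

    def test_inconsistent_replicates_excluded(self):
        # pooled fold > 4 but the direction reverses in one replicate pair
        counts = {
            ("1.1.1.1", "s1"): 900,
            ("1.1.1.1", "s2"): 10,  # this root replicate is below soil
            ("1.1.1.1", "s3"): 100,
            ("1.1.1.1", "s4"): 100,
        }
        for s in ("s1", "s2", "s3", "s4"):
            counts[("9.9.9.9", s)] = 10000 - counts[("1.1.1.1", s)]
        profile = _profile(counts)
        da, db = select_differential(profile, DESIGN_DF, "root", "soil")
        assert "1.1.1.1" not in da.enzymes and "1.1.1.1" not in db.enzymes

    def test_symmetry(self):
        profile = balanced_profile({"1.1.1.1": (100, 10), "2.2.2.2": (5, 80)})
        da, db = select_differential(profile, DESIGN_DF, "root", "soil")
        db2, da2 = select_differential(profile, DESIGN_DF, "soil", "root")
        assert da.enzymes == da2.enzymes
        assert db.enzymes == db2.enzymes

    def test_identical_counts_give_empty_sets(self):
        profile = balanced_profile({"1.1.1.1": (50, 50), "2.2.2.2": (7, 7)})
        da, db = select_differential(profile, DESIGN_DF, "root", "soil")
        assert not da.enzymes and not db.enzymes

    def test_unknown_environment_rejected(self):
        profile = balanced_profile({"1.1.1.1": (5, 5)})
        with pytest.raises(ValidationError):
            select_differential(profile, DESIGN_DF, "root", "mars")

    def test_external_table_mode(self):
        profile = balanced_profile({"1.1.1.1": (5, 5), "2.2.2.2": (5, 5)})
        table = pd.DataFrame(
            {
                "enzyme": ["1.1.1.1", "2.2.2.2"],
                "log2fc": [3.0, -0.5],
                "fdr": [0.001, 0.001],
            }
        )
        da, db = select_differential(
            profile, DESIGN_DF, "root", "soil", external_table=table
        )
        assert da.enzymes == {"1.1.1.1"}
        assert not db.enzymes  # |log2fc| 0.5 is below the 2-fold cut
        assert da.provenance == "external"
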