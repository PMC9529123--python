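"""Annotation-resource loaders and indexed queries."""

import logging

import pytest

from acmghl.core import GenomicVariant
from acmghl.resources import (
    ClinVarRecord,
    ClinVarSignificance,
    ResourceError,
    load_resources,
)
from acmghl.resources import _load_bed_track  # loader internals under test


def test_loader_round_trip_matches_in_memory_bundle(fixture_set, fixture_dir, bundle):
    loaded = load_resources(fixture_dir / "resources.yaml")
    assert set(loaded.transcripts) == set(bundle.transcripts)
    for tid, t in bundle.transcripts.items():
        lt = loaded.transcripts[tid]
        assert (lt.exons, lt.cds_start, lt.cds_end, lt.strand) == (
            t.exons, t.cds_start, t.cds_end, t.strand
        )
        assert lt.clinically_significant_exons == t.clinically_significant_exons
    assert len(loaded.clinvar) == len(bundle.clinvar)
    assert set(loaded.af) == set(bundle.af)
    for key, rec in bundle.af.items():
        assert loaded.af[key].af_by_subpopulation == pytest.approx(
            rec.af_by_subpopulation
        )
    assert loaded.inheritance == bundle.inheritance
    assert loaded.exclusion == bundle.exclusion


def test_track_queries_agree_with_naive_scan(fixture_set, bundle):
    chrom_len = len(fixture_set.genome_seqs["chr1"])
    probes = [(s, s + 25) for s in range(0, chrom_len, 97)]
    for name, intervals in fixture_set.tracks.items():
        for start, end in probes:
            naive = sorted(
                (s, e, lbl)
                for s, e, lbl in intervals
                if s < end and e > start
            )
            assert bundle.query_track(name, "chr1", start, end) == naive


def test_clinvar_codon_query_at_exon_junction(fixture_set, bundle):
    """The junction codon's split genomic positions are all searched."""
    t = bundle.transcripts["TOYB-T1"]
    gene = fixture_set.genes["TOYB"]
    # codon 33 spans the junction between coding exons 1 and 2
    positions = t.codon_genomic_positions(33)
    exon_of = [
        {i for i, (s, e) in enumerate(t.exons) if s <= g < e} for g in positions
    ]
    assert exon_of[0] != exon_of[-1], "codon 33 should straddle two exons"
    hits = bundle.query_clinvar_codon(t, 33, min_stars=1)
    assert len(hits) == 1 and hits[0].hgvs_p == "p.Arg34Ile"
    assert bundle.query_clinvar_codon(t, 33, min_stars=5) == []


def test_clinvar_codon_query_filters_opposite_strand(bundle):
    t = bundle.transcripts["TOYB-T1"]
    rec = bundle.query_clinvar_codon(t, 33, min_stars=1)[0]
    flipped = ClinVarRecord(
        rec.chrom, rec.pos, rec.ref, rec.alt, rec.significance,
        rec.review_stars, rec.hgvs_p, "+",
    )
    from acmghl.resources import ResourceBundle

    b2 = ResourceBundle(
        genome=bundle.genome,
        transcripts=bundle.transcripts,
        clinvar=[flipped],
    )
    assert b2.query_clinvar_codon(t, 33, min_stars=1) == []


def test_clinvar_range_star_filter(fixture_set, bundle):
    gene = fixture_set.genes["TOYF"]
    lo, hi = gene.cds_to_g(0), gene.cds_to_g(89) + 1
    hits = bundle.query_clinvar_range(
        "chr1", lo, hi,
        significance_filter={ClinVarSignificance.PATHOGENIC}, min_stars=1,
    )
    assert len(hits) == 1
    assert bundle.query_clinvar_range(
        "chr1", lo, hi,
        significance_filter={ClinVarSignificance.PATHOGENIC}, min_stars=2,
    ) == []
    assert bundle.query_clinvar_range("chr1", lo, lo) == []


def test_af_exact_lookup(fixture_set, bundle):
    pv = next(p for p in fixture_set.panel if p.vid == "v02")
    rec = bundle.query_af(pv.variant)
    assert rec is not None and len(rec.af_by_subpopulation) == 3
    # key-based lookup: any variant not in the table is absent
    novel = GenomicVariant("chr1", 1, "A", "T")
    assert bundle.query_af(novel) is None


def test_bed_rows_with_invalid_intervals_rejected(tmp_path, caplog):
    bed = tmp_path / "bad.bed"
    bed.write_text("chr1\t100\t50\tbackwards\nchr1\t10\t20\tok\n")
    with caplog.at_level(logging.WARNING):
        trees = _load_bed_track(bed)
    assert "row 1 rejected" in caplog.text
    assert len(trees["chr1"]) == 1


def test_missing_mandatory_resource_names_criteria(fixture_dir, tmp_path):
    import yaml

    cfg = yaml.safe_load((fixture_dir / "resources.yaml").read_text())
    cfg = {
        k: (str(fixture_dir / v) if not isinstance(v, dict)
            else {n: str(fixture_dir / p) for n, p in v.items()})
        for k, v in cfg.items()
    }
    del cfg["clinvar"]
    with pytest.raises(ResourceError, match="PS1, PM5"):
        load_resources(cfg)
    cfg2 = dict(cfg)
    cfg2["clinvar"] = str(fixture_dir / "clinvar.tsv")
    del cfg2["af"]
    with pytest.raises(ResourceError, match="PM2, BA1 and BS1"):
        load_resources(cfg2)


def test_empty_inheritance_map_defaults_to_unknown(fixture_dir):
    import yaml

    from acmghl.resources import InheritanceMode

    cfg = yaml.safe_load((fixture_dir / "resources.yaml").read_text())
    cfg = {
        k: (str(fixture_dir / v) if not isinstance(v, dict)
            else {n: str(fixture_dir / p) for n, p in v.items()})
        for k, v in cfg.items()
    }
    empty = fixture_dir / "inheritance_empty.tsv"
    empty.write_text("gene_symbol\tmode\n")
    cfg["inheritance"] = str(empty)
    loaded = load_resources(cfg)
    assert loaded.inheritance == {}
    assert loaded.inheritance_mode("TOYA") is InheritanceMode.UNKNOWN
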