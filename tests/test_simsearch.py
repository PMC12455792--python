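"""Translation, the built-in local-alignment engine, tabular-6 I/O and hit filters."""

import numpy as np
import pytest

from ocgkit.config_io import ParseError, SequenceRecord, ValidationError
from ocgkit.simsearch import (
    BuiltinEngine,
    SimilarityHit,
    collect_candidate_orthologs,
    filter_hits,
    parse_tabular6,
    translate_cds,
    write_tabular6,
)
from ocgkit.synthdata import SyntheticSpec, generate_families


def make_hit(**kw) -> SimilarityHit:
    base = dict(
        query_id="A", subject_id="B", pident=95.0, aln_length=150,
        mismatches=5, gap_opens=0, q_start=1, q_end=150, s_start=1,
        s_end=150, evalue=1e-30, bitscore=250.0,
    )
    base.update(kw)
    return SimilarityHit(**base)


class TestTranslate:
    @pytest.mark.parametrize(
        "cds, pep",
        [
            ("ATG", "M"),
            ("ATGGCTTAA", "MA"),      # trailing stop stripped
            ("ATGTAAGCT", "MXA"),     # internal stop -> X
            ("ATGGCTTA", "MA"),       # trailing remainder ignored
        ],
    )
    def test_frame_one_standard_code(self, cds, pep):
        assert translate_cds(cds) == pep

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            translate_cds("AT")


class TestFilterHits:
    @pytest.mark.parametrize(
        "kw, kept",
        [
            ({}, True),
            ({"bitscore": 100.0}, False),           # must exceed 100
            ({"bitscore": 100.01}, True),
            ({"pident": 80.0}, False),              # must exceed 80
            ({"aln_length": 100}, False),           # must surpass 100
            ({"aln_length": 101}, True),
            ({"evalue": 1e-5}, True),               # must not exceed -> inclusive
            ({"evalue": 1.1e-5}, False),
            ({"subject_id": "A"}, False),           # self-hit
        ],
    )
    def test_default_boundaries(self, kw, kept):
        assert (filter_hits([make_hit(**kw)]) == [make_hit(**kw)]) is kept

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(0)
        hits = [
            make_hit(
                query_id=f"q{i}",
                subject_id=f"s{rng.integers(5)}",
                bitscore=float(rng.uniform(50, 300)),
                pident=float(rng.uniform(50, 100)),
                aln_length=int(rng.integers(50, 300)),
                evalue=float(10.0 ** -rng.uniform(0, 40)),
            )
            for i in range(100)
        ]
        once = filter_hits(hits)
        assert set(h.query_id for h in once) <= set(h.query_id for h in hits)
        assert filter_hits(once) == once
        # order preserved
        idx = [hits.index(h) for h in once]
        assert idx == sorted(idx)


class TestTabular6:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("A\tB\t95.5\t120\t5\t1\t1\t120\t3\t122\t1e-30\t250\n")
        (h,) = parse_tabular6(p)
        assert (h.pident, h.aln_length, h.s_start, h.bitscore) == (95.5, 120, 3, 250.0)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert parse_tabular6(p) == []

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("\t".join(["x"] * 11) + "\n")
        with pytest.raises(ParseError, match=":1"):
            parse_tabular6(p)

    def test_round_trip(self, tmp_path):
        hits = [make_hit(query_id=f"q{i}", bitscore=100.0 + i) for i in range(5)]
        p = tmp_path / "hits.tsv"
        write_tabular6(hits, p)
        assert parse_tabular6(p) == hits


@pytest.fixture(scope="module")
def engine():
    return BuiltinEngine()


@pytest.fixture(scope="module")
def family_peptides():
    """Planted families translated to peptides, keyed by family index."""
    from ocgkit.simsearch import translate_cds as tr

    spec = SyntheticSpec(n_species=3, n_families=4, seed=11)
    cds, family_of, _ = generate_families(spec)
    peps = [
        SequenceRecord(r.seq_id, tr(r.sequence), r.species_id)
        for sp in spec.species_ids()
        for r in cds[sp]
    ]
    return peps, family_of


class TestBuiltinEngine:
    def test_identical_sequences_full_identity(self, engine):
        seq = "MKV" * 67  # ~200 aa
        recs = [SequenceRecord("a", seq), SequenceRecord("b", seq)]
        hits = engine.search([recs[0]], [recs[1]])
        (h,) = hits
        assert h.pident == 100.0
        assert h.aln_length == len(seq)
        assert h.q_start == 1 and h.q_end == len(seq)

    def test_score_symmetric(self, engine):
        rng = np.random.default_rng(1)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        a = SequenceRecord("a", "".join(rng.choice(list(aas), 120)))
        b = SequenceRecord("b", "".join(rng.choice(list(aas), 120)))
        hab = engine.search([a], [b])
        hba = engine.search([b], [a])
        assert hab[0].bitscore == pytest.approx(hba[0].bitscore)

    def test_self_search_contains_diagonal(self, engine):
        recs = [SequenceRecord(f"s{i}", "MKVLWAAL" * 20) for i in range(3)]
        hits = engine.search(recs, recs)
        diag = {(h.query_id, h.subject_id) for h in hits if h.query_id == h.subject_id}
        assert diag == {(f"s{i}", f"s{i}") for i in range(3)}

    def test_unrelated_random_sequences_filtered_out(self, engine):
        rng = np.random.default_rng(2)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        a = SequenceRecord("a", "".join(rng.choice(list(aas), 100)))
        b = SequenceRecord("b", "".join(rng.choice(list(aas), 100)))
        assert filter_hits(engine.search([a], [b])) == []

    def test_planted_families_yield_only_within_family_edges(
        self, engine, family_peptides
    ):
        peps, family_of = family_peptides
        hits = filter_hits(engine.search(peps, peps))
        assert hits, "expected within-family hits to survive the filters"
        for h in hits:
            assert family_of[h.query_id] == family_of[h.subject_id]
        # and every family is internally connected by at least one hit
        fams_hit = {family_of[h.query_id] for h in hits}
        assert fams_hit == set(family_of.values())


class TestExternalEngine:
    @pytest.mark.skipif(
        __import__("shutil").which("blastp") is None, reason="blastp not installed"
    )
    def test_blastp_adapter_agrees_with_builtin_on_planted_families(
        self, engine, family_peptides
    ):
        """NCBI blastp as independent aligner: after the default filters it
        must connect exactly the same within-family pairs as the built-in
        Smith-Waterman engine (e-values/bitscores differ; the filtered
        edge set must not)."""
        from ocgkit.simsearch import ExternalEngine

        peps, family_of = family_peptides
        external = ExternalEngine("blastp")
        edges_ext = {
            frozenset((h.query_id, h.subject_id))
            for h in filter_hits(external.search(peps, peps))
        }
        edges_builtin = {
            frozenset((h.query_id, h.subject_id))
            for h in filter_hits(engine.search(peps, peps))
        }
        assert edges_ext == edges_builtin
        for e in edges_ext:
            a, b = tuple(e)
            assert family_of[a] == family_of[b]


class TestCollectOrthologs:
    def test_candidate_with_orthologs_collected_once(self, engine, family_peptides):
        peps, family_of = family_peptides
        proteomes: dict[str, list[SequenceRecord]] = {}
        for p in peps:
            proteomes.setdefault(p.species_id, []).append(p)
        # family 0 members of the first species are the "candidates"
        sp0 = sorted(proteomes)[0]
        cands = [p.seq_id for p in proteomes[sp0] if family_of[p.seq_id] == 0]
        collection, coexp_ids = collect_candidate_orthologs(
            {sp0: cands}, proteomes, engine
        )
        ids = [r.seq_id for r in collection]
        assert len(ids) == len(set(ids))  # dedup
        assert set(cands) <= set(ids)
        assert coexp_ids == set(cands)
        # all collected non-candidates belong to family 0 (the only query family)
        for r in collection:
            assert family_of[r.seq_id] == 0
        # orthologs from the other species were pulled in
        assert {r.species_id for r in collection} == set(proteomes)

    def test_duplicate_ids_across_species_rejected(self, engine):
        rec = SequenceRecord("same", "MKVLWAAL" * 20, "sp1")
        rec2 = SequenceRecord("same", "MKVLWAAL" * 20, "sp2")
        with pytest.raises(ValidationError):
            collect_candidate_orthologs(
                {"sp1": ["same"]}, {"sp1": [rec], "sp2": [rec2]}, engine
            )
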