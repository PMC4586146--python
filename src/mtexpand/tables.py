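"""Published golden-jackal haplotype tables, embedded as package fixtures.

Two mtDNA haplotype tables for the golden jackal (*Canis aureus*), as
printed in the source study's variable-site tables:

* control region (CR), 440 bp locus: 18 haplotypes x 27 variable sites
  (coordinates on the *Canis lupus lupus* reference mitogenome NC_009686),
  16 Indian haplotypes plus one each from Israel and Europe;
* cytochrome *b* (cyt b), 412 bp locus: 9 haplotypes x 9 variable sites,
  40 individuals in total.

Locality codes: Indian states Gujarat (GJ), Uttar Pradesh (UP), Rajasthan
(RJ), Uttarakhand (UA), Haryana (HR), Karnataka (KR), Madhya Pradesh (MP)
and Central India (CI); plus Israel and the European countries pooled into
the widespread monomorphic European haplotype.

The printed CR locality counts for India sum to 52, while the diversity
table of the same study analyses n = 51 Indian sequences (one individual was
evidently excluded, which one is not stated).  ``jackal_cr_table`` therefore
exposes both readings via ``as_analyzed``.
"""

from __future__ import annotations

import io

from .hapio import HaplotypeTable, read_haplotype_table

__all__ = [
    "jackal_cr_table",
    "jackal_cytb_table",
    "reference_tables",
    "CR_LENGTH",
    "CYTB_LENGTH",
    "INDIA_LOCALITIES",
    "EUROPE_LOCALITIES",
]

#: aligned locus lengths (bp) of the sequenced fragments
CR_LENGTH = 440
CYTB_LENGTH = 412

INDIA_LOCALITIES = frozenset({"GJ", "UP", "RJ", "UA", "HR", "KR", "MP", "CI"})
EUROPE_LOCALITIES = frozenset({"Bulgaria", "Serbia", "Croatia", "Italy", "Austria"})

_CR_TSV = """\
haplotype_id	site:15465	site:15466	site:15485	site:15494	site:15498	site:15510	site:15518	site:15527	site:15528	site:15529	site:15530	site:15531	site:15536	site:15586	site:15611	site:15613	site:15619	site:15621	site:15629	site:15633	site:15634	site:15636	site:15639	site:15654	site:15711	site:15750	site:15751	count:GJ	count:UP	count:RJ	count:UA	count:HR	count:KR	count:MP	count:CI	count:Israel	count:Bulgaria	count:Serbia	count:Croatia	count:Italy	count:Austria
Ind1	C	-	A	G	T	T	A	C	-	-	C	T	T	A	G	T	A	T	C	T	T	A	C	A	C	A	C	2	3	3	0	0	0	0	0	0	0	0	0	0	0
Ind2	C	C	A	G	C	T	-	T	-	-	C	C	T	A	G	T	A	T	C	T	T	A	C	G	C	A	C	4	0	0	0	0	0	0	0	0	0	0	0	0	0
Ind3	C	C	A	G	C	T	-	T	T	T	C	C	C	A	G	T	A	T	C	T	T	A	C	G	C	A	C	4	0	0	0	0	0	0	0	0	0	0	0	0	0
Ind4	C	-	A	G	T	T	A	C	-	-	C	T	T	A	G	T	A	T	C	T	T	A	C	G	C	A	T	0	1	0	0	0	0	0	0	0	0	0	0	0	0
Ind5	C	-	A	G	T	C	-	C	-	-	C	T	T	A	G	T	A	T	C	T	T	A	C	G	T	A	C	16	0	0	0	0	0	0	0	0	0	0	0	0	0
Ind6	C	-	A	A	T	T	A	C	-	-	C	T	T	G	G	T	A	T	C	T	T	A	C	A	T	A	C	0	1	0	0	0	0	0	0	0	0	0	0	0	0
Ind7	C	-	A	G	T	T	A	C	-	-	C	T	T	A	G	T	A	T	C	T	T	A	C	A	T	A	C	0	0	0	0	2	0	0	0	0	0	0	0	0	0
Ind8	C	C	A	G	T	T	-	C	-	-	C	T	T	A	G	T	A	T	C	T	T	A	C	G	T	A	C	2	0	0	1	0	0	0	0	0	0	0	0	0	0
Ind9	C	-	A	G	T	T	A	C	-	-	C	T	T	A	G	C	A	T	C	T	C	A	C	G	C	A	C	0	0	0	0	0	3	0	0	0	0	0	0	0	0
Ind10	C	-	A	G	T	T	A	C	-	-	C	T	T	G	A	T	A	T	C	T	T	A	C	G	C	A	C	0	0	0	0	0	0	2	0	0	0	0	0	0	0
Ind11	C	-	A	G	T	T	A	C	-	-	C	T	T	A	G	T	A	T	C	T	T	A	C	G	C	A	C	0	1	0	0	0	0	0	0	0	0	0	0	0	0
Ind12	C	-	A	G	T	T	-	C	-	-	T	C	T	A	G	T	A	T	T	T	T	A	C	A	C	A	C	0	1	0	0	0	0	0	0	0	0	0	0	0	0
Ind13	C	-	A	G	T	T	A	C	C	-	C	T	T	A	G	T	G	T	C	T	T	A	C	G	C	A	T	0	1	0	0	0	0	0	0	0	0	0	0	0	0
Ind14	C	-	G	G	T	T	A	C	-	-	C	T	T	A	G	T	A	T	C	T	T	A	T	A	T	A	C	0	0	0	0	0	0	1	0	0	0	0	0	0	0
Ind15	C	-	A	G	T	T	A	C	-	-	C	T	T	G	G	T	A	T	C	T	T	A	C	G	T	A	C	0	1	0	1	0	0	0	0	0	0	0	0	0	0
Ind16	-	-	A	G	T	T	A	C	-	-	C	T	T	A	G	T	A	T	C	C	T	G	C	A	C	A	C	0	0	0	0	0	0	0	2	0	0	0	0	0	0
Isr	C	-	A	G	T	T	A	C	-	-	C	T	T	G	G	T	A	C	C	T	T	A	C	A	T	A	C	0	0	0	0	0	0	0	0	2	0	0	0	0	0
Eur	C	-	A	G	T	T	A	C	-	-	C	T	T	G	G	T	A	T	C	T	T	A	C	G	T	G	C	0	0	0	0	0	0	0	0	0	60	129	50	7	1
"""

_CYTB_TSV = """\
haplotype_id	site:14279	site:14289	site:14319	site:14334	site:14352	site:14360	site:14393	site:14571	site:14669	count:UP	count:UA	count:HR	count:RJ	count:GJ	count:MP	count:KR	count:CI	count:Israel	count:Bulgaria
cytb_Ind01	T	T	C	T	T	G	T	A	G	6	1	2	2	0	0	0	0	0	0
cytb_Ind02	T	T	C	T	T	G	T	G	G	2	0	0	0	3	2	0	0	0	0
cytb_Ind03	T	T	C	T	C	G	T	G	G	0	0	0	0	6	0	0	0	0	0
cytb_Ind04	T	T	C	T	T	G	T	G	A	0	0	0	0	0	0	2	0	0	0
cytb_Ind05	T	T	C	T	T	G	C	G	G	0	0	0	0	3	0	0	0	0	0
cytb_Ind06	T	C	C	T	T	G	T	G	G	0	2	0	0	0	0	0	0	0	0
cytb_Ind07	T	T	T	T	T	A	T	G	G	0	0	0	0	0	0	0	2	0	0
cytb_Isr	T	T	C	C	T	G	T	G	G	0	0	0	0	0	0	0	0	2	0
cytb_Blg	A	T	C	C	T	G	T	G	G	0	0	0	0	0	0	0	0	0	5
"""


def _parse(tsv: str) -> HaplotypeTable:
    import tempfile, os

    # read_haplotype_table takes a path; round through a temp file so the
    # embedded fixtures exercise the same parser as user-supplied tables
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False, encoding="utf-8") as fh:
        fh.write(tsv)
        path = fh.name
    try:
        return read_haplotype_table(path)
    finally:
        os.unlink(path)


def jackal_cr_table(as_analyzed: bool = False) -> HaplotypeTable:
    """The 18-haplotype control-region table.

    With ``as_analyzed=False`` (default) the locality counts are exactly as
    printed (India sums to 52).  With ``as_analyzed=True`` one Gujarat
    individual of the most frequent haplotype (Ind5) is dropped so the Indian
    sample size matches the n = 51 used in the study's diversity table; which
    individual the study actually excluded is not recorded, so this choice is
    arbitrary but deterministic.
    """
    tbl = _parse(_CR_TSV)
    if as_analyzed:
        counts = [list(row) for row in tbl.counts]
        i = tbl.haplotype_ids.index("Ind5")
        j = tbl.localities.index("GJ")
        counts[i][j] -= 1
        tbl = HaplotypeTable(
            haplotype_ids=tbl.haplotype_ids,
            sites=tbl.sites,
            states=tbl.states,
            localities=tbl.localities,
            counts=tuple(tuple(row) for row in counts),
        )
    return tbl


def jackal_cytb_table() -> HaplotypeTable:
    """The 9-haplotype cytochrome-b table (40 individuals)."""
    return _parse(_CYTB_TSV)


def reference_tables() -> dict[str, HaplotypeTable]:
    """Both packaged tables, keyed ``cr_table`` / ``cytb_table``."""
    return {"cr_table": jackal_cr_table(), "cytb_table": jackal_cytb_table()}
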