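"""7mer-m8 seed-site scanning of miRNA seeds against 3'-UTR sequences.

A canonical 7mer-m8 site is an exact Watson-Crick match in the 3'-UTR to
positions 2-8 (5' -> 3') of the mature miRNA, reverse-complemented onto
the UTR sense strand.  No G:U wobble and no 6mer/8mer site classes are
considered: only perfect 7mer-m8 pairing validates a candidate
miRNA->mRNA co-expression edge.
"""

from __future__ import annotations

import logging

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_RNA_OK = set("ACGUT")


def seed_site(mature_sequence: str) -> str:
    """DNA match site for a mature miRNA: reverse complement of bases 2-8.

    Accepts RNA or DNA alphabet, case-insensitively; U and T are
    equivalent.  The returned 7-mer is what must occur verbatim on the UTR
    sense strand.
    """
    seq = mature_sequence.strip().upper()
    if len(seq) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {mature_sequence!r}")
    bad = set(seq) - _RNA_OK
    if bad:
        raise ValueError(f"invalid base {sorted(bad)[0]!r} in mature sequence")
    seed = seq[1:8].replace("U", "T")
    return str(Seq(seed).reverse_complement())


def scan_sites(site: str, utr_sequence: str) -> list[int]:
    """All 1-based start positions of exact (possibly overlapping) matches.

    Ambiguity codes never match; scanning is on the given sense strand
    only, so UTRs must already be sense-oriented.
    """
    utr = utr_sequence.strip().upper().replace("U", "T")
    site = site.upper()
    positions = []
    start = utr.find(site)
    while start != -1:
        positions.append(start + 1)
        start = utr.find(site, start + 1)
    return positions


def read_fasta(path) -> dict[str, list[str]]:
    """FASTA records keyed by id (header up to first whitespace).

    Multiple records per id (UTR isoforms) are kept, longest first.
    """
    records: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records.setdefault(rec.id, []).append(str(rec.seq))
    for seqs in records.values():
        seqs.sort(key=len, reverse=True)
    return records


def seed_filter_edges(
    edges: pd.DataFrame, utr_fasta, mirna_fasta
) -> pd.DataFrame:
    """Keep miRNA->mRNA edges only when a 7mer-m8 site exists in the UTR.

    A match in any UTR isoform of the gene validates the edge; mRNA-mRNA
    edges pass through untouched.  Edges whose mRNA has no UTR record are
    logged and treated as non-validated.
    """
    utrs = read_fasta(utr_fasta)
    matures = read_fasta(mirna_fasta)
    keep_rows = []
    for idx, e in edges.iterrows():
        if e["edge_type"] != "miRNA->mRNA":
            keep_rows.append((idx, pd.NA, 0))
            continue
        mirna, mrna = e["source"], e["target"]
        if mirna not in matures:
            raise KeyError(f"miRNA {mirna!r} absent from mature FASTA")
        if mrna not in utrs:
            logger.warning("no UTR record for %s: edge treated as non-validated", mrna)
            keep_rows.append((idx, False, 0))
            continue
        site = seed_site(matures[mirna][0])
        n_sites = sum(len(scan_sites(site, u)) for u in utrs[mrna])
        keep_rows.append((idx, n_sites > 0, n_sites))
    out = edges.copy()
    out["seed_validated"] = pd.Series(
        {i: v for i, v, _ in keep_rows}, dtype="object"
    )
    out["n_sites"] = pd.Series({i: n for i, _, n in keep_rows})
    drop = out["seed_validated"].eq(False) & (out["edge_type"] == "miRNA->mRNA")
    return out[~drop].copy()
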