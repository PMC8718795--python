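"""Translation-start-site extraction from GFF3 gene models.

The TLS is the first base of the start codon: for a + strand gene the
minimum CDS start of the representative (first) transcript, for a -
strand gene the maximum CDS end.
"""

from __future__ import annotations

import gffutils

from timgo.io_data import GeneAnnotation


def read_gene_annotations(gff_path) -> dict[str, GeneAnnotation]:
    """Gene ID -> TLS annotation for every gene in a GFF3 file."""
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    out: dict[str, GeneAnnotation] = {}
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene  # representative transcript
        cds = list(db.children(parent, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        if gene.strand == "+":
            tls = min(c.start for c in cds)
        elif gene.strand == "-":
            tls = max(c.end for c in cds)
        else:
            continue
        out[gene.id] = GeneAnnotation(gene.id, gene.seqid, tls, gene.strand)
    return out
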