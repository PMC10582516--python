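# External reference datasets (user-supplied)

The full test suite exercises three published reference networks that cannot be
redistributed here. To run those checks, deposit the following plain-text files
in this directory; everything else in the suite is self-contained and runs on
synthetic data.

| file | contents | source |
| --- | --- | --- |
| `masc_edges.tsv` | two-column edge list (Entrez IDs) of the MASC / NMDA-receptor-complex PPI network: 101 proteins, 246 interactions | Husi et al. (2000) proteomics of the mammalian NMDA receptor complex; curated edge list as redistributed with later network re-analyses |
| `diseasome_bipartite.tsv` | two-column disease–gene association table (disease name, gene symbol) of the human "diseasome" | Goh et al. (2007) *PNAS* 104:8685, supplementary table S1 |
| `presynaptic_edges.tsv` | two-column edge list (Entrez IDs) of a presynaptic-compartment PPI network (LCC: 1780 vertices, 6620 edges) | presynaptic proteome studies integrated via the Synaptome.db Bioconductor resource |

Format notes: tab-separated, optional single header row, one interaction per
line. IDs are treated as opaque strings.
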