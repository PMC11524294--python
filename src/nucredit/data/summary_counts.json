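{
  "description": "Reference counts from the published poplar nuclear RNA-editing survey, used as worked-example fixtures.",
  "region_site_counts": {"5UTR": 2300, "CDS": 18133, "3UTR": 4220},
  "total_sites": 24653,
  "cds_four_type_counts": {"A-to-G": 2769, "G-to-A": 2854, "C-to-U": 2909, "U-to-C": 2974},
  "cds_four_type_total": 11506,
  "endosymbiont": {"edited": 1922, "total": 7036, "reported_pct": 27.3, "other_pct": 19.5},
  "go_examples": [
    {"term": "CUL4-RING ubiquitin ligase complex", "k_edited": 75, "term_size": 132, "reported_pct": 56.8},
    {"term": "exocyst", "k_edited": 19, "term_size": 30, "reported_pct": 63.3}
  ],
  "est": {"covered": 2171, "confirmed": 1157, "reported_pct": 53.3},
  "chloroplast": {"second_codon_position_sites": 18, "c_to_u_sites": 19, "total": 20},
  "clusters": {"edited_gene_total": 546, "ppr_total": 46}
}
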