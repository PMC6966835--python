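"""Published summary inputs from the fasted-vs-fed Duroc gilt muscle study.

The study contrasts gluteus medius transcriptomes of fasted gilts (AL-T0,
n = 11) against gilts slaughtered 5 h (AL-T1, n = 12) or 7 h (AL-T2,
n = 12) after feeding.  These constants are the printed per-contrast
summary counts and the fold changes of the miRNAs called differentially
expressed in the AL-T0/AL-T1 contrast; they serve as worked-example
inputs for the summary statistics implemented in :mod:`nutrinet.de`.
"""

# (number of DE genes, number of expressed genes analysed) per contrast
DE_COUNTS = {
    "mrna_fasted_fed5h": (149, 10648),
    "mrna_fasted_fed7h": (435, 10714),
    "mirna_fasted_fed5h": (6, 286),
    "mirna_fasted_fed7h": (28, 286),
}

# log2 fold changes of the six DE miRNAs in the fasted vs fed-5h contrast
DE_MIRNA_LOG2FC_FASTED_FED5H = [0.9978, 0.8568, 0.9229, 0.8989, 0.7686, 1.2420]
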