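# DBD lengths stated in prose for specific genes (the census text names the
# smallest and largest DBDs per gene); used by the cross-table discrepancy report.
gene	dbd_len_text
GhHsf24	83
GhHsf29	83
GhHsf30	83
GhHsf40	83
GhHsf33	105
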