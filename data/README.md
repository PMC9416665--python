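Drop plain-text UniProt FASTA fixtures here (P78536.fasta, P16471.fasta).
With network access: python scripts/fetch_data.py
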