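Place the *Ruegeria pomeroyi* DSS-3 replicon sequences here as FASTA
(`NC_003911.fa`, `NC_006569.fa`) to enable the real-genome acceptance
checks in `tests/test_acceptance.py`.  The files are ~4.6 Mb and are not
distributed with the package.
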