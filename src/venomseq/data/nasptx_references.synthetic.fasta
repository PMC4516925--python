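>synthetic-ref-1a family=NaSpTx1 synthetic=true
QCFGVYWDCWGPAPYCCKMSCMLLQWAMECKWSHF
>synthetic-ref-1b family=NaSpTx1 synthetic=true
QCTVVNWDCWGPDHYCCKMSCMLLQWAMECKMSVR
>synthetic-ref-1c family=NaSpTx1 synthetic=true
QCFVVYHLCWKPAHYCCKMSCMLDQWAMECKMSHR
>synthetic-ref-2a family=NaSpTx2 synthetic=true
PCVEQYNNCTSRCCEQWCHEVFRHNCDINPQEHWKLY
>synthetic-ref-2b family=NaSpTx2 synthetic=true
PCVEQRMNCTSKCCEWWCHEWFRHNCHIDPQEHWKIY
>synthetic-ref-2c family=NaSpTx2 synthetic=true
PCFEQRNWCTSRCCEQWCHEVFRHNCHINPQEYWKIY
>synthetic-ref-3a family=NaSpTx3 synthetic=true
DCKDTVPCTLNFCCVPQWFCFPWRCFMTYL
>synthetic-ref-3b family=NaSpTx3 synthetic=true
DCKETVPCILNFCCNPQWPCFPWRCFMLYS
>synthetic-ref-3c family=NaSpTx3 synthetic=true
DCKDKVPCTLNFCCVPQWSCFPWRCFHLRS
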