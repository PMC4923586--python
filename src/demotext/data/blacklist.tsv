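# Misclassified (surface form, concept) pairs suppressed during annotation:
# surface <TAB> concept_id. Grow this file from the frequency report when a
# generic surface trips a dictionary entry it should not.
i	C0282488
human	C0086418
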