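# Primate species panel with divergence times from the human lineage (My).
# gibbon (~20 My) and rhesus (~30 My) are the speciation times the analysis
# hinges on; the remaining defaults are field-standard values and are meant
# to be overridden per study.
species	divergence_My	source
chimp	6	default
gorilla	9	default
orangutan	16	default
gibbon	20	stated
rhesus	30	stated
marmoset	43	default
squirrel_monkey	43	default
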