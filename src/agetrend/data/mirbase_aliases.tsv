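old_name	new_name
hsa-miR-93*	hsa-miR-93-3p
hsa-miR-23a*	hsa-miR-23a-5p
hsa-miR-25*	hsa-miR-25-5p
hsa-miR-149*	hsa-miR-149-3p
hsa-miR-150*	hsa-miR-150-3p
hsa-miR-425*	hsa-miR-425-3p
hsa-miR-500	hsa-miR-500a-5p
hsa-miR-500*	hsa-miR-500a-3p
hsa-miR-26b*	hsa-miR-26b-3p
hsa-miR-30e*	hsa-miR-30e-3p
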