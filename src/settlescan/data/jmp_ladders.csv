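service,code,rung
water,piped_on_premises,safely_managed
water,piped_to_yard,basic
water,public_tap,basic
water,tubewell_borehole,basic
water,protected_well,basic
water,protected_spring,basic
water,rainwater,basic
water,public_tap_far,limited
water,unprotected_well,unimproved
water,unprotected_spring,unimproved
water,tanker_truck,unimproved
water,surface_water,surface
sanitation,flush_to_sewer,safely_managed
sanitation,flush_to_septic,basic
sanitation,pit_latrine_slab,basic
sanitation,composting_toilet,basic
sanitation,shared_improved,limited
sanitation,pit_latrine_no_slab,unimproved
sanitation,hanging_latrine,unimproved
sanitation,bucket,unimproved
sanitation,open_defecation,open_defecation
hygiene,handwashing_water_soap,basic
hygiene,handwashing_water_only,limited
hygiene,handwashing_no_water,limited
hygiene,no_facility,no_facility
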