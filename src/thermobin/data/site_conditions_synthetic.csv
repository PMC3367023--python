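# Synthetic five-site outflow transect: temperature cooling from a boiling
# alkaline source pool toward a phototrophic mat zone, pH rising ~1 unit.
site_id,temperature_c,ph
site1,92.0,7.3
site2,85.0,7.5
site3,72.0,7.8
site4,62.0,8.1
site5,56.0,8.3
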