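# Example docking search box covering the whole internal cavity of an
# ABC-transporter transmembrane bundle (xy = membrane plane), Å.
center: [0.0, 0.0, 0.0]
extents: [32.25, 26.25, 37.50]
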