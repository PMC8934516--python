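# Van der Waals radii (A) used by the solvent-accessible surface area
# calculation; elements not listed fall back to the carbon radius.
element	radius
C	1.70
N	1.55
O	1.52
S	1.80
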