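# Reference coordinates

The open/closed-state structure predictions (accessible-volume inter-dye
distances at sites 82/222 and the open-minus-closed buried surface) run
on the public PDB entries:

- `1EFC.pdb` — EF-Tu in the GDP-bound open state
- `1EXM.pdb` — EF-Tu in the GTP-analog closed state

These files are not redistributed with the package.  Download them from
the PDB (https://www.rcsb.org/) and place them in this directory; the
two structure acceptance tests and the `conformo sasa` / `conformo av`
examples will then operate on the real coordinates.
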