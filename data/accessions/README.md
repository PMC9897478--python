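# Public accession files

Checks against the deposited channel structures and measured SEC-SANS
curves look for the following files in this directory (lower-case stems):

- `7q3g.pdb` / `7q3h.pdb` — cryo-EM models with and without calcium
  (Protein Data Bank entries 7Q3G, 7Q3H; `.cif` also accepted)
- `6v4s.pdb` / `6v4a.pdb` — closed and open X-ray models (PDB 6V4S, 6V4A)
- `sasdng5.dat` / `sasdnh5.dat` — reduced SEC-SANS curves with and without
  calcium (SASBDB entries SASDNG5, SASDNH5; 3-column `Q I sigma` ASCII)

None of these are bundled with the package; download them from the public
archives (rcsb.org, sasbdb.org) to enable the deposition-gated tests.
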