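# Deposited coordinate files (not distributed)

The published-metric reproduction (`analysis/04_reproduce_deposited.py` and
the deposited-structure checks in `tests/test_acceptance.py`) operates on
the tropomyosin Tpm(Cdc8) cable crystal structures, which are too large to
ship here and are fetched from the PDB:

```sh
curl -o data/structures/8puz.cif https://files.rcsb.org/download/8PUZ.cif
curl -o data/structures/8pv0.cif https://files.rcsb.org/download/8PV0.cif
curl -o data/structures/9ff9.cif https://files.rcsb.org/download/9FF9.cif
```

- `8puz.cif` — unacetylated conformer U1 (one dimer, space group P1)
- `8pv0.cif` — unacetylated conformers U2 and U3 (two dimers, P2₁)
- `9ff9.cif` — acetylated conformer A1 (one dimer, P1)
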