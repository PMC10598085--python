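>CLP1_EN synthetic domain template
ADDQSHVALLSEFFVPRTRYLSTDNHTAFEIERAMARAEGYKTPAGGSNMNELKSGAPAK
AQVFASSLDNEYTFLEDNPKTQMLVIRRGAGNLADIMNYLSKTSRVLANLTRQVRVAMLE
>CLP1_P synthetic domain template
KSANTINECIVRGSAGTGKSLVVIFIANESTLGIKGKQLNVVPKSLVDKLAITSYAGAIL
VFDEPLYEWTDLGEENCIQTFADAIGEDRHALNVPGVGHEYKLTTCSNRWVEHGFWMTFV
LERMKLNKKRGPLLPTMKLGLITFKPLKRKTEFGTVQFAATSYDQIASEP
>CLP1_EC synthetic domain template
LKGGFKRFTTPKHSDKRRQERAVLVEEMVLKVGFGSKVVMLNPLGQYASGSVSCQAMLWP
AYPGAYTPPEISTGHVELDEALNQSIHDLQRHRTAGMIIPVVEAMNDALADPGGQKTKRD
IETEANVNYF
>CLP1_EUC1 synthetic domain template
TVTTKRSVRTSIREDNTAKSASTYRFGIGISIEQFVGLPTFVEAEKKIQSPVLNTLAVRE
NVEMVAEPTKGFEYEGYCIAASYLSGATTDLGPTPATATPLAADLFHQYDVGSAGDSATE
PRMERVKLEDSALWSDDSYMSHTIL
>CLP1_EUC2 synthetic domain template
TVEAKIIALPPQGHSPDFLPDFSALGEPDTSVTHEMPQVHEDMDPEFELYHLHAGLLEAI
QRNEDMAEPVEQSSGLIPPDVITESSSATEQCTVKKDLGTTKWFKKQAEEGAIAGDENMQ
QCHLQELPLAPNKIKQGTAVQQSSEVLKHT
>CLP1_EUC3 synthetic domain template
TKEGSECRWKVVPPAQTVRDRLGAPLKPVAFAALHHHIEVTEGLKFDRGLKIRACNLHLD
SLEYQIFNDLQVVINKPQPLAGLNGDVNGLPPPLGHKACSHGYFKFAANKDLSLVLGQMN
HDFKVYGEVMAAGAETAYMG
>NOL9_EN synthetic domain template
KYFPRVSVMSAVQRARDGVKEKRMKYLIQVFILIWISTNDMADPPAFFAQLEGGEDLLQY
MLPSMDIVYVDHEADPTNIMAKRGTGLTVSQVELTSLYPR
>NOL9_EC synthetic domain template
FKARILMLKDQDRLEAMAAEIYKVPLSVARAWQTTQWRYKTKMLFDTDSISGLTIASNDP
TIMVAKSREYGHEGSTKQKAWTKGQISIYGVEYAVSRSLKLDERFNVADAECFSDEAHKL
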