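>COL1A1_SYNTHETIC collagen alpha-1(I)-like precursor scaffold, 1464 aa (synthetic; embeds published urinary-fragment coordinates; not the natural sequence)
MFSFVDLRLLLLLAATALLTHGNETATDVTCDYRQCTYHFVTEVHPGLKLEPNDEEQLSH
IDMKAGFYVAGFCFFHWHAKEVSNNDCMTMKEHYWMAFWTYHDNGTKHPCWECYSWTCNW
EEVFKMNMCQVECTFCKFRDAEQRPFEMNCPVRRWTRQIQVQLSYGYDEKSTGGISVPGK
EGPRGQFGPPGEPGAPGLFGKEGSAGVDGPSGEEGKPGSFGGKGSAGANGDDGEAGKPGR
PGERGPPGPQGDQGKDGKLGQFGDQGDEGADGLDGAKGDAGPAGPKGEPGSPGENGAPGQ
MGPRGQTGPSGARGKFGRAGLEGGDGENGSGGQRGGNGNDGDEGERGSEGTEGRKGLLGL
AGQAGDEGSPGQAGALGELGSKGAEGDPGSPGQSGVEGKKGKEGKEGPGGFPGDRGEAGP
DGAKGPKGDKGPAGQTGEEGQAGFGGKEGSQGQEGKSGAQGGDGTQGKVGPEGVGGNVGT
AGEPGAQGKRGATGEPGSLGNRGVLGDGGPTGAFGKGGSKGPPGSEGKDGNAGGPGAPGS
TGSPGSPGPDGKTGPPGPAGPFGRPGNPGRLGQTGTPGTEGPGGRSGKKGDEGDEGSKGE
GGSNGESGARGPKGERGLVGGVGAEGAKGSLGSAGPNGSQGKAGLPGPAGPPGEAGKPGE
QGVPGDLGAPGPSGARGEFGEAGDSGFKGPQGDGGRDGPKGQAGPLGDKGPPGERGAKGF
AGKVGPPGRTGKDGGDGPVGPEGKAGAAGEGGVKGARGQPGGGGLTGPIGPPGPAGAPGD
KGESGPSGPAGPTGKPGSAGLPGFAGPPGPAGFAGPPGADGQPGAKGEPGDAGAKGDAGP
PGPAGPAGPPGPIGKSGDSGPSGPPGTPGAEGFGGDFGTEGQVGEPGKNGKAGRAGEKGS
KGKEGGKGPRGETGPAGRPGEVGPPGPPGPAGEKGSPGADGPAGAPGFGGAEGQRGDSGF
KGRAGQKGRDGRDGEKGPKGDSGVSGRPGREGDPGRVGVNGVEGAGGADGDAGFKGPQGA
EGSPGRDGSPGAKGGSGASGLFGPKGSPGFPGNEGEFGDSGADGAPGSPGPKGADGPEGP
KGELGPGGQVGAKGGDGPPGARGRDGSGGDSGSQGFDGSGGEPGPFGAEGPPGKNGENGV
AGRPGAVGNVGVEGDPGKAGAGGGPGAKGPFGSQGRPGREGPTGSEGQAGPDSAGFDFSF
LPQPPQEKAHDGGRYYRALPYLTPKLHYLMPICYHFHMMNPNVSQWGCNDNWHQNSYTRE
YLLTPTKRMAKWRSAWQPELGVDMIKACFWPHGVCDNSEGMEWNCHWDRWQRNPFLQASD
NNYYLNTIWMRQWRCGRPERSPLQLSSSEGRNLKGQSRHLEVKFFIKYGHWMNYIAVLEL
TWMDAVSTPSRMIDYSMPKIVEVLWTNQANSQRIWSAYTFFQAVLSWENRHAETHDFGEN
CGNERCELHQMKKRGLVFKQMACE
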