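>CASB_BOVIN signal_length=15 source_accession=P02666 name=beta-casein_(bovine),_mature_A2_variant
RELEELNVPGEIVESLSSSEESITRINKKIEKFQSEEQQQTEDELQDKIHPFAQTQSLVY
PFPGPIPNSLPQNIPPLTQTPVVVPPFLQPEVMGVSKVKEAMAPKHKEMPFPKYPVEPFT
ESQSLTLTDVENLHLPLPLLQSWMHQPHQPLPPTVMFPPQSVLSLSQSKVLPVPQKAVPY
PQRDMPIQAFLLYQEPVLGPVRGPFPIIV
>CASA1_BOVIN signal_length=15 source_accession=P02662 name=alpha-s1-casein_(bovine),_mature_B_variant
RPKHPIKHQGLPQEVLNENLLRFFVAPFPEVFGKEKVNELSKDIGSESTEDQAMEDIKQM
EAESISSSEEIVPNSVEQKHIQKEDVPSERYLGYLEQLLRLKKYKVPQLEIVPNSAEERL
HSMKEGIHAQQKEPMIGVNQELAYFYPELFRQFYQLDAYPSGAWYYVPLGTQYTDAPSFS
DIPNPIGSENSEKTTMPLW
>CASA2_BOVIN signal_length=15 source_accession=P02663 name=alpha-s2-casein_(bovine),_mature_A_variant
KNTMEHVSSSEESIISQETYKQEKNMAINPSKENLCSTFCKEVVRNANEEEYSIGSSSEE
SAEVATEEVKITVDDKHYQKALNEINQFYQKFPQYLQYLYQGPIVLNPWDQVKRNAVPIT
PTLNREQLSTSEENSKKTVDMESTEVFTKKTKLTEEEKNRLNFLKKISQRYQKFALPQYL
KTVYQHQKAMKPWIQPKTKVIPYVRYL
>CASK_BOVIN signal_length=21 source_accession=P02668 name=kappa-casein_(bovine),_mature_A_variant
QEQNQEQPIRCEKDERFFSDKIAKYIPIQYVLSRYPSYGLNYYQQKPVALINNQFLPYPY
YAKPAAVRSPAQILQWQVLSNTVPAKSCQAQPTTMARHPHPHLSFMAIPPKKNQDKTEIP
TINTIASGEPTSTPTTEAVESTVATLEDSPEVIESPPEINTVQVTSTAV
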