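gene	control_001	control_002	control_003	control_004	control_005	control_006	control_007	control_008	control_009	control_010	case_001	case_002	case_003	case_004	case_005	case_006	case_007	case_008	case_009	case_010
G00	7.8561326177314434	8.481470040595084	8.558747247847238	8.126894371033822	8.16565367681431	7.804180078597911	7.634351718067644	7.639855748387605	7.600627492804586	8.371681929637584	7.257804032820961	7.506636584452762	8.246994547408775	6.956908325143218	7.725728961326564	8.18391447177941	8.130940621178846	7.966905019439012	7.70582825670854	8.24009977428502
G01	7.942445477220369	8.169323722727842	7.8908588168843465	7.610043416978401	7.575449870642728	7.6252759809102315	8.141302913747978	7.9176671139550585	7.7237963184078895	7.9996338542476035	7.562052188673355	7.673239714337097	7.053824982102548	7.7869640390362305	7.574725278911651	7.724142478498915	6.81551761967387	7.2390169801248385	7.639119889138889	7.241107035417712
G02	7.4153451013691605	8.60281763821998	7.713464723406141	8.08657125871298	8.901949118070213	6.995818823822724	7.339574040668785	7.6207268224906715	7.945895037872996	7.457231608524305	8.233259307323937	8.816765469246466	8.011950149553403	8.13203522839784	7.817684760240644	7.828920427709585	7.43165433984091	8.211524143613047	7.451357738197174	7.798932486587495
G03	7.883755226346576	7.9500277707426	7.798202570433514	6.955565750042799	8.103144062475907	8.396548467468257	8.270729286410074	7.793805096380811	7.804940197711138	6.865009631432761	7.75578436348829	7.491345655638245	7.617778152219856	7.954004174729571	8.365119318500128	7.923696337968609	8.39457549046875	8.044695337383843	7.997463444233716	8.085733810330632
G04	8.186757038866105	8.457929496263255	8.099053989673584	6.918947034505589	7.924883270673327	7.998122746612166	7.841995341439956	8.47262576558658	7.486752103894073	7.604132740824782	6.860639652444778	7.321883188640616	7.004379878898563	7.022148759552708	7.659776007029297	6.585405863421801	6.578727712619463	6.927503861639437	7.06281223610144	6.816167595725177
G05	8.216614318015075	8.214068213634226	7.900328699389941	8.56505658573898	8.283612049511982	7.628370658036483	8.534005183464233	7.8496145751311905	7.586648736909719	8.09257733022289	7.331278203582116	7.088533635682699	7.09625367520648	6.4736228521856125	7.613040520067692	6.9679806531349815	6.6336597423523935	7.504146105295677	6.957229392050297	6.673755726274553
G06	8.285477657510441	8.582231808740147	7.992092639660452	8.126338168718473	7.52738174942987	7.503129540033804	7.778212764697207	7.038354294969211	7.814574590170606	7.4870353070221185	7.713924926566833	8.374420978005675	7.710682763692518	7.716133334196393	7.843791852626325	7.797086969222621	7.440876946122039	8.37192016461768	8.205658462839173	8.324256254254417
G07	8.526267722005413	8.438277416831546	8.416503050093013	7.571722386240776	7.44074473624245	7.382998690616958	7.947855174803286	7.907755548080382	7.512175389168183	7.844587395709558	7.74693065441306	7.888335540164553	7.4269840020815066	7.825407116530673	7.883761246224576	7.909346149186406	7.723917429228393	8.190905297456165	7.984815282536753	8.099089259519465
G08	8.184773182657057	8.47823633851982	8.25083753546833	7.96074470976151	7.0866535360970895	7.181045485590097	7.720897046373629	7.438782628073615	7.970063186226802	7.761358252885158	8.115198399385434	7.180063072874503	7.56723584329724	7.703571025453687	8.181643503776725	7.984932852429765	7.569132915357267	8.517859691079977	8.006269692548058	7.965266714958767
G09	8.227864506940579	8.314262188418025	8.951795463258945	7.988934886826793	8.427371238677427	8.29711371156438	7.324253990346774	7.113411470197385	8.350937539028527	8.1932552085391	6.660049359135468	7.07029044247262	7.21188745466438	7.133127897866419	6.901749431374236	6.219763631570305	7.474526913812973	6.136294657383353	6.751070462599403	6.197276539904091
G10	8.92693919152399	7.542788113524406	8.037316466813978	8.08685432732114	7.120985617961735	8.26448664813733	7.902691808634693	7.560522395327415	8.846917923938483	7.5931328955241915	7.760555497394235	7.717712241042549	8.763335503700407	7.542551438700736	6.899585863231586	7.9934717386349945	7.855850237897601	8.434966382493585	8.282259725860683	7.282258811354502
G11	7.903325173784384	7.55200101407904	7.345999422102206	8.391462648019866	8.151422053084694	7.217689404977786	7.554092210754013	8.68168519642724	8.654730799378111	7.77193565307126	7.88515845915828	7.726535553821784	7.884569388820321	7.874904510579832	7.68076424252107	8.164269135720398	7.358848779922917	7.637057144354567	8.45987360689198	8.492678681163763
G12	7.951118909883314	7.250289186891987	7.910861004174749	8.882259138945123	7.835992814700324	8.69234123118643	8.738777487666521	7.637046038310674	8.073863101517018	8.205143955724285	7.986736912447401	8.543054951493914	8.41326924225046	8.38180384083359	7.66141441038795	7.904691830748207	8.749034989687633	7.860351893763758	7.737327031369672	8.213188180868816
G13	8.063017059313713	7.607057190993429	8.386011707928652	7.76133855125799	8.58656320596226	8.07200067296382	8.239509658066597	8.285265239810126	7.591564834224173	8.337067668859914	7.779315596054341	8.475850646247572	8.05304268970865	7.9422368632756575	8.069797784846465	8.05171493887223	7.505527102697649	7.413832139032702	7.9292807202572355	7.6934138418545555
G14	7.665764743437715	7.39108400443518	7.793873857321079	8.206974976127329	7.611833881024643	8.017254645328638	8.115957994637162	8.394364031141706	7.507536014740377	7.8817683507531395	8.525888975717153	7.684221542282348	7.719907283816704	8.66843851403503	8.049453932728275	8.473508952881325	7.987349959707869	8.572630333855692	8.583481799644206	8.927236318698487
G15	7.0892535496251	7.195548023719878	8.116626031698168	7.660533095090102	8.753400744274353	7.557095910287443	7.87361592591108	8.213613267064439	7.393036431101298	8.221101370635033	8.011161207497755	8.27414779704046	7.7987466141658	9.01399855326294	8.261688669241511	7.4849291354577385	8.830153889965963	7.6218939315419405	6.847086275720468	8.425766412877572
G16	8.355791175081723	8.208380101296257	8.171114032793476	8.131241902509926	7.867098853219416	8.058622378345579	7.496382444557398	7.885501594826526	7.382878592627777	8.137498871490244	7.725048719087937	8.027999545705587	8.002053677113778	8.103661579235675	8.33235048476341	7.3958626044933435	9.12946975522252	8.356439509097283	8.101796015075019	8.355808978926708
G17	7.908478313399603	7.9500021033105	7.781379447716716	7.661073189299333	7.744620950764477	8.291277794323198	7.977079789333259	8.526702276199417	8.411142070904582	7.833228997124304	8.982402162425435	9.01620303303277	9.237973927049628	9.423626009338244	8.813086837833843	9.322409923976625	8.962665430261477	8.796403388243672	9.051706815444911	8.753315907371103
G18	7.701677897555454	7.498530494430448	8.16235662306946	7.894800416387957	7.580487096828814	7.804443000729529	7.810247113348364	8.586720500258629	8.452841489439622	8.167889650434812	7.900747789842761	7.815242540916988	7.776794627826523	7.933266960505696	8.057341418477854	7.727836475939738	7.635670790861427	8.34416724923796	7.642756625506752	7.9523772666824915
G19	8.044138676434008	7.8221150214666135	8.073404363543883	7.361510666077086	7.963999100188938	8.495075515376024	8.067658464836834	8.447280489685948	7.97026568965936	7.40933571155295	8.052647353846638	7.619152014358605	8.333402325572628	7.89940664963209	7.798527825514039	8.399131041011882	7.473902374542465	7.419776120556701	7.893890009558849	7.92182407834937
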