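pos	rsid	FAM3-a	FAM3-b	FAM1-a	FAM1-b	FAM2-a	FAM2-b	61224-a	61224-b	61244-a	61244-b	61030-a	61030-b	61334-a	61334-b	61328-a	61328-b	61031-a	61031-b
107600949	rs3828085	A	A	A	A	G	G	A	A	A	A	A	A	A	A	G	G	G	G
107605964	rs9804074	G	G	G	G	A	A	G	G	G	G	G	G	G	G	G	G	G	G
107639225	rs6693140	T	T	T	T	T	T	T	T	T	T	T	T	T	T	C	C	T	T
107642995	rs4550085	T	T	T	T	C	C	T	T	T	T	T	T	T	T	C	C	T	T
107647631	rs12127467	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	A	A
107665660	rs4378232	T	T	T	T	C	C	T	T	T	T	T	T	T	T	C	C	C	C
107701229	rs12043814	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	T	T
107702788	rs2494066	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	T	T
107704426	rs2494070	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	G	G
107708701	rs12403629	T	T	C	C	C	C	T	T	T	T	C	C	C	C	C	C	C	C
107726008	rs4503376	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
107726179	rs17019810	C	C	C	C	T	T	T	T	T	T	C	C	C	C	C	C	C	C
107739098	rs7519428	G	G	A	A	G	G	G	G	G	G	G	G	G	G	A	A	G	G
107762256	rs4415601	T	T	G	G	G	G	G	G	G	G	T	T	T	T	G	G	T	T
107772515	rs4462178	T	T	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
107782599	rs10881483	T	T	C	C	T	T	T	T	T	T	T	T	T	T	C	C	T	T
107788674	rs11576720	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	C	C
107811048	rs17020104	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
107813378	rs17485868	G	G	A	A	G	G	G	G	G	G	A	A	A	A	G	G	G	G
107836421	rs4460667	G	G	G	G	A	A	A	A	A	A	G	G	G	G	A	A	A	A
107843782	rs1380445	T	T	T	T	G	G	G	G	G	G	T	T	-	-	G	G	G	G
107855772	rs13373947	A	A	A	A	G	G	G	G	G	G	A	A	A	A	A	A	A	A
107882433	rs345292	A	A	A	A	G	G	G	G	G	G	G	G	G	G	G	G	A	A
107888320	rs11185201	C	C	C	C	C	C	C	C	C	C	T	T	T	T	C	C	C	C
107899020	rs17020294	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
107905580	rs10494083	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	C	C
107924764	rs345306	G	G	T	T	T	T	T	T	T	T	G	G	G	G	T	T	T	T
107932019	rs17020387	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
107941495	rs17020437	T	T	C	C	C	C	C	C	C	C	T	T	T	T	C	C	T	T
107968879	rs404634	C	C	C	C	C	C	C	C	C	C	C	C	-	-	C	C	T	T
107988189	rs12569255	T	T	T	T	T	T	T	T	T	T	T	T	-	-	T	T	T	T
107995780	rs12563016	G	G	G	G	G	G	G	G	G	G	T	T	-	-	G	G	G	G
108011539	rs1777467	A	A	A	A	A	A	A	A	A	A	G	G	G	G	A	A	A	A
108029484	rs4915093	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G
108071266	rs1343192	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108073978	rs10494087	A	A	A	A	A	A	A	A	A	A	G	G	G	G	A	A	A	A
108092662	rs12034547	T	T	T	T	T	T	T	T	T	T	G	G	G	G	T	T	T	T
108098283	rs2336126	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
108111706	rs501273	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
108113616	rs614499	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
108119014	rs1660419	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108120673	rs1777450	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108137612	rs17513833	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108168646	rs829004	C	C	C	C	C	C	C	C	C	C	C	C	C	C	T	T	T	T
108183767	rs597999	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
108198443	rs594397	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
108211211	rs7538977	T	T	T	T	T	T	T	T	T	T	T	T	T	T	C	C	C	C
108328623	rs1417300	T	T	T	T	T	T	T	T	T	T	T	T	T	T	C	C	C	C
108504914	rs10776805	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G
108527234	rs12036929	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108531271	rs11101974	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
108566144	rs1353721	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
108583777	rs17024373	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G
108588401	rs970860	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108716296	rs11102288	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108717735	rs4970804	A	A	A	A	A	A	A	A	A	A	A	A	-	-	A	A	A	A
108722941	rs4970808	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
108760685	rs4970811	G	G	G	G	G	G	G	G	G	G	G	G	G	G	A	A	A	A
108816336	rs6696787	C	C	C	C	C	C	C	C	C	C	C	C	C	C	T	T	T	T
108816880	rs1277213	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G
108820610	rs1333130	T	T	T	T	T	T	T	T	T	T	T	T	T	T	C	C	C	C
108841814	rs10857972	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108854607	rs12405585	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108866143	rs2131905	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108943574	rs338466	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
108950376	CLCC1-MUTATION	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
108963067	rs550743	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108970652	rs11803800	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
108972406	rs12032662	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
108973113	rs570812	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
109142651	rs587727	G	G	A	A	G	G	G	G	G	G	G	G	G	G	G	G	G	G
109154346	rs595635	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
109171781	rs17014495	A	A	A	A	A	A	C	C	C	C	C	C	C	C	C	C	C	C
109196449	rs2478762	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
109197926	rs2296696	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
109206449	rs3197233	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
109209582	rs604500	C	C	T	T	C	C	C	C	C	C	C	C	C	C	C	C	C	C
109229079	rs669697	C	C	A	A	C	C	C	C	C	C	C	C	C	C	C	C	C	C
109240933	rs4246519	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
109246091	rs17035443	G	G	A	A	G	G	G	G	G	G	G	G	G	G	G	G	G	G
109262024	rs4970833	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G
109289661	rs655246	G	G	A	A	G	G	A	A	A	A	A	A	A	A	A	A	A	A
109338099	rs11102972	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
109369429	rs17646665	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
109381055	rs12037569	G	G	G	G	G	G	T	T	T	T	T	T	T	T	T	T	T	T
109473110	rs10494040	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
109505814	rs3738772	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C	C
109513504	rs6677291	C	C	C	C	C	C	T	T	T	T	T	T	T	T	T	T	T	T
109519003	rs534135	C	C	T	T	C	C	C	C	C	C	C	C	C	C	C	C	C	C
109778808	rs12239350	-	-	-	-	-	-	C	C	T	T	T	T	T	T	C	C	C	C
109883546	rs875903	-	-	-	-	-	-	G	G	A	A	G	G	G	G	G	G	G	G
110000402	rs720917	-	-	-	-	-	-	T	T	T	T	T	T	T	T	T	T	T	T
110104236	rs11576956	-	-	-	-	-	-	G	G	A	A	G	G	G	G	A	A	G	G
110234421	rs11102065	-	-	-	-	-	-	C	C	T	T	C	C	C	C	T	T	C	C
110278256	rs752653894	-	-	-	-	-	-	T	T	T	T	T	T	T	T	T	T	T	T
110330874	rs61787370	-	-	-	-	-	-	T	T	C	C	T	T	T	T	C	C	T	T
110472417	rs11102121	-	-	-	-	-	-	C	C	C	C	C	C	C	C	C	C	T	T
110628756	rs2640491	-	-	-	-	-	-	C	C	T	T	T	T	-	-	T	T	C	C
111136919	rs1030926216	-	-	-	-	-	-	T	T	G	G	T	T	-	-	T	T	G	G
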